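# Default functional-category predicates for the class x category matrices.
#
# Each category matches a gene when any of its GO ids equals one of the
# gene's GO ids, or any term substring occurs (case-insensitively) in one of
# the gene's GO term texts.  Categories may overlap; a gene counts in every
# category it matches.  Entries with a `parent` are sub-families whose
# percentages are taken over the parent category's per-class count (used for
# the transcription-factor family sub-table).
#
# The row set approximates the published distribution tables; the biological
# GO -> category mapping is intentionally editable because no canonical
# mapping ships with the data.
categories:
  - name: Membrane-associated
    go_ids: [GO:0016020]
    term_substrings: [membrane]
  - name: Chloroplast
    go_ids: [GO:0009507]
    term_substrings: [chloroplast]
  - name: Thylakoid membrane
    go_ids: [GO:0009535]
    term_substrings: [thylakoid]
  - name: RESP. Aba/Salt/Cold/Heat
    go_ids: [GO:0009737, GO:0009651, GO:0009409, GO:0009408]
    term_substrings:
      - response to abscisic acid
      - response to salt
      - response to cold
      - response to heat
  - name: Response to light
    go_ids: [GO:0009416]
    term_substrings: [response to light]
  - name: Response to JA
    go_ids: [GO:0009753]
    term_substrings: [response to jasmonic acid]
  - name: Response to SA
    go_ids: [GO:0009751]
    term_substrings: [response to salicylic acid]
  - name: Response to Auxin
    go_ids: [GO:0009733]
    term_substrings: [response to auxin]
  - name: Response to ethylene
    go_ids: [GO:0009723]
    term_substrings: [response to ethylene]
  - name: Response to GA
    go_ids: [GO:0009739]
    term_substrings: [response to gibberellin]
  - name: Lea
    term_substrings: [late embryogenesis abundant]
  - name: Ribosomal and protein synthesis
    go_ids: [GO:0005840, GO:0006412]
    term_substrings: [ribosom, translation]
  - name: Protein degradation
    go_ids: [GO:0030163]
    term_substrings: [proteolysis, protein catabolic]
  - name: Transcription factors
    go_ids: [GO:0003700]
    term_substrings: [transcription factor]
  - name: AP2/ERF
    parent: Transcription factors
    term_substrings: [ap2/erf, ethylene-responsive transcription factor]
  - name: bHLH
    parent: Transcription factors
    term_substrings: [bhlh transcription factor]
  - name: bZIP
    parent: Transcription factors
    term_substrings: [bzip transcription factor]
  - name: HD-like
    parent: Transcription factors
    term_substrings: [homeobox, hd-zip]
  - name: MYB
    parent: Transcription factors
    term_substrings: [myb transcription factor]
  - name: ZF
    parent: Transcription factors
    term_substrings: [zinc finger transcription factor]
  - name: NAC
    parent: Transcription factors
    term_substrings: [nac domain transcription factor]
  - name: GRAS
    parent: Transcription factors
    term_substrings: [gras transcription factor]
  - name: HSF
    parent: Transcription factors
    term_substrings: [heat shock transcription factor]
  - name: CCAAT
    parent: Transcription factors
    term_substrings: [ccaat-binding transcription factor]
  - name: WRKY
    parent: Transcription factors
    term_substrings: [wrky transcription factor]
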