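# Default two-cluster / two-subcluster grouping of the eight lime accessions.
clusters:
  Bhutanese:
    - Bhutan-09015
    - Bhutan-09024
    - Bhutan-09027
    - Bhutan-09030
  Indonesian:
    - Bhutan-09005
    - Indonesia-88065
    - Indonesia-88035
    - Indonesia-88045
subclusters:
  Indonesian:
    subcluster1:
      - Bhutan-09005
      - Indonesia-88065
    subcluster2:
      - Indonesia-88035
      - Indonesia-88045
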