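# Default SpCas9 domain map: residue ranges (inclusive) to domain and
# contiguous-domain labels, following the canonical SpCas9 architecture
# (discontinuous RuvC nuclease split into RuvC-I/II/III, REC lobe with the
# REC-II insertion inside REC-I, bridge helix BH, HNH nuclease and the
# PAM-interacting (PI) domain).  Edit or replace this file to re-map domains
# for other Cas9 orthologs or numbering conventions.
segments:
  - {start: 1,    end: 56,   domain: RuvC, contiguous: RuvC-I}
  - {start: 57,   end: 93,   domain: BH,   contiguous: BH}
  - {start: 94,   end: 179,  domain: REC,  contiguous: REC-I}
  - {start: 180,  end: 307,  domain: REC,  contiguous: REC-II}
  - {start: 308,  end: 717,  domain: REC,  contiguous: REC-I}
  - {start: 718,  end: 774,  domain: RuvC, contiguous: RuvC-II}
  - {start: 775,  end: 908,  domain: HNH,  contiguous: HNH}
  - {start: 909,  end: 1099, domain: RuvC, contiguous: RuvC-III}
  - {start: 1100, end: 1368, domain: PI,   contiguous: PI}
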