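# Lookup from descriptor-slug keywords to parent descriptor classes.
#
# A feature name has the form Cas9_<residue>_<descriptor slug>[_<GN|SW|WNA|VD>].
# The slug (aggregation token removed) is matched against the keywords below;
# the longest matching keyword wins, so e.g. "entropy_density" resolves to ED
# before the bare "density" keyword can claim it.  Slugs matching no keyword
# are annotated with parent class "unknown" (a warning is logged).
#
# Parent classes: 18 total -- 4 standalone (Accessibility, DSSP,
# Hydrophobicity, STRIDE) and 14 that occur with the four neighbour
# aggregations GN / SW / WNA / VD, giving 4 + 14*4 = 60 descriptor classes.
keywords:
  accessibility: Accessibility
  dssp: DSSP
  hydrophobicity: Hydrophobicity
  stride: STRIDE
  cross_link: CLO
  cross_link_order: CLO
  cross_presence: CPO
  cross_presence_order: CPO
  curvature: Curv
  density: Density
  contact_energy: CED
  contact_energy_density: CED
  electrostatic: EP
  electrostatic_potential: EP
  entropy: ED
  entropy_density: ED
  graph: GD
  graph_descriptor: GD
  residue_contacts: RC
  side_chain: SCO
  side_chain_angle: SCO
  side_chain_orientation: SCO
  solvation: Solv
  sponge: Sponge
  unused_contacts: UC
  weighted_contact: WCN
  weighted_contact_number: WCN
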