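# Default chamber-array dPCR chip: 54 parallel channels, 108 rows of 198
# cylindrical chambers (21,384 total), 87 um diameter x 120 um height
# (~0.71 nL each).  Pitch is a rendering parameter only.
layout:
  n_channels: 54
  n_rows: 108
  chambers_per_row: 198
  chamber_diameter: 87.0
  chamber_height: 120.0
  channel_width: 60.0
  channel_height: 55.0
  pitch_x: 110.0
  pitch_y: 110.0

# Four-colour panel: universal reference probe on Cy5 plus three
# codon-12 mutation probes, one per remaining channel.
panel:
  channels: [Cy5, FAM, HEX, ROX]
  reference_channel: Cy5
  target_map:
    G12S: FAM
    G12D: HEX
    G12V: ROX
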