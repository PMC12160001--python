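# Shipped solvent database.
# relative_permittivity: CRC values at 20 C, pinned; the 1:1 water/methanol
# arithmetic mean is 56.52. Molecular volumes are computed on load from the
# template geometries with the same convex-hull convention used for solutes.
water:
  relative_permittivity: 80.10
  template: water.xyz
methanol:
  relative_permittivity: 32.94
  template: methanol.xyz
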