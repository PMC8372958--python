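# Synthetic stand-in for an 8-level rainbow calibration bead set
# (RCP-30-5A-like).  These MEF levels are NOT vendor values: they match the
# defaults of the cytogate synthetic-data generator.  Replace the numbers
# with the vendor-supplied calibration sheet for real bead lots.
name: synthetic-rainbow-8
levels:
  BL1-A: [90.0, 260.0, 700.0, 1900.0, 5200.0, 14000.0, 38000.0, 105000.0]
  YL1-A: [70.0, 200.0, 560.0, 1500.0, 4200.0, 11500.0, 31000.0, 85000.0]
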