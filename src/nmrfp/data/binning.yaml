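# Default chemical-shift binning grid.
# 0.2-10.0 ppm at 0.05 ppm width = 196 raw bins; the exclusion windows below
# drop 40 bins (residual water, sporadic ethanol contamination, noisy edges),
# retaining 156.
lo: 0.2
hi: 10.0
width: 0.05
exclusions:
  - name: residual water
    window: [4.50, 5.15]      # 13 bins
  - name: ethanol CH3 triplet
    window: [1.10, 1.25]      # 3 bins
  - name: ethanol CH2 quartet
    window: [3.60, 3.70]      # 2 bins
  - name: downfield noise trim
    window: [9.00, 10.00]     # 20 bins
  - name: upfield noise trim
    window: [0.20, 0.30]      # 2 bins
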