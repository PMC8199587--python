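# Packaged serum metabolite/macromolecule signature library (32 signals).
#
# Chemical-shift positions follow standard serum assignments (e.g. lactate
# doublet 1.33 ppm, alanine doublet 1.48 ppm, glutamine multiplet 2.44 ppm,
# anomeric glucose doublet 5.24 ppm, histidine ring protons 7.05/7.75 ppm).
# Positions, linewidths, relative heights, quantification windows and baseline
# concentrations are fixture data for the synthetic generator and the
# quantification windows of the univariate screen -- not analytical claims.
#
# peaks: [center_ppm, relative_height, linewidth_ppm] (Lorentzian, area-normalised
#        per peak so that window integrals are proportional to concentration).
# effect_size: default signed Cliff's delta between early and metastatic serum
#        (positive = lower in metastatic samples).
# base_concentration: arbitrary units; log-normal median for the healthy-like group.
signatures:
  - name: Glutamine
    weight_class: small_molecule
    peaks: [[2.430, 0.5, 0.012], [2.455, 0.5, 0.012]]
    quant_window: [2.40, 2.50]
    base_concentration: 0.60
    effect_size: 0.330
  - name: Histidine
    weight_class: small_molecule
    peaks: [[7.05, 0.6, 0.012], [7.75, 0.4, 0.012]]
    quant_window: [7.00, 7.10]
    base_concentration: 0.10
    effect_size: 0.280
  - name: Formate
    weight_class: small_molecule
    peaks: [[8.44, 1.0, 0.010]]
    quant_window: [8.40, 8.48]
    base_concentration: 0.04
    effect_size: -0.212
  - name: Alanine
    weight_class: small_molecule
    peaks: [[1.470, 0.5, 0.010], [1.490, 0.5, 0.010]]
    quant_window: [1.44, 1.52]
    base_concentration: 0.45
    effect_size: 0.168
  - name: Proline
    weight_class: small_molecule
    peaks: [[2.000, 1.0, 0.012]]
    quant_window: [1.96, 2.03]
    base_concentration: 0.20
    effect_size: 0.168
  - name: Valine
    weight_class: small_molecule
    peaks: [[0.980, 0.5, 0.010], [1.040, 0.5, 0.010]]
    quant_window: [1.02, 1.06]
    base_concentration: 0.25
    effect_size: 0.163
  - name: 3-methyl-2-oxovalerate
    weight_class: small_molecule
    peaks: [[1.100, 0.7, 0.010], [0.890, 0.3, 0.010]]
    quant_window: [1.08, 1.13]
    base_concentration: 0.03
    effect_size: -0.163
  - name: Tyrosine
    weight_class: small_molecule
    peaks: [[6.900, 0.5, 0.012], [7.190, 0.5, 0.012]]
    quant_window: [6.86, 6.94]
    base_concentration: 0.07
    effect_size: 0.139
  - name: Acetate
    weight_class: small_molecule
    peaks: [[1.920, 1.0, 0.010]]
    quant_window: [1.89, 1.95]
    base_concentration: 0.05
    effect_size: -0.137
  - name: Glucose
    weight_class: small_molecule
    peaks:
      - [5.2369, 0.09, 0.012]
      - [5.2431, 0.09, 0.012]
      - [3.410, 0.20, 0.025]
      - [3.480, 0.22, 0.025]
      - [3.720, 0.22, 0.025]
      - [3.850, 0.14, 0.025]
      - [4.650, 0.04, 0.012]
    quant_window: [3.40, 3.55]
    base_concentration: 5.00
    effect_size: 0.126
  - name: Isoleucine
    weight_class: small_molecule
    peaks: [[0.930, 0.6, 0.010], [1.000, 0.4, 0.010]]
    quant_window: [0.91, 0.95]
    base_concentration: 0.07
    effect_size: 0.117
  - name: 3-hydroxybutyrate
    weight_class: small_molecule
    peaks: [[1.190, 0.5, 0.010], [2.310, 0.3, 0.012], [4.140, 0.2, 0.012]]
    quant_window: [1.16, 1.22]
    base_concentration: 0.08
    effect_size: -0.107
  - name: Leucine
    weight_class: small_molecule
    peaks: [[0.955, 0.5, 0.012], [0.965, 0.5, 0.012]]
    quant_window: [0.94, 0.98]
    base_concentration: 0.13
    effect_size: 0.103
  - name: Glycoproteins
    weight_class: macromolecule
    peaks: [[2.040, 1.0, 0.050]]
    quant_window: [2.00, 2.08]
    base_concentration: 4.00
    effect_size: 0.097
  - name: Lactate
    weight_class: small_molecule
    peaks: [[1.325, 0.4, 0.008], [1.340, 0.4, 0.008], [4.110, 0.2, 0.010]]
    quant_window: [1.30, 1.36]
    base_concentration: 2.00
    effect_size: -0.093
  - name: "Lipoproteins βCH2"
    weight_class: macromolecule
    peaks: [[1.580, 1.0, 0.200]]
    quant_window: [1.50, 1.66]
    base_concentration: 8.00
    effect_size: 0.075
  - name: Lipoproteins N(CH3)3
    weight_class: macromolecule
    peaks: [[3.220, 1.0, 0.120]]
    quant_window: [3.18, 3.26]
    base_concentration: 5.00
    effect_size: 0.073
  - name: cholesterol
    weight_class: macromolecule
    peaks: [[0.700, 1.0, 0.150]]
    quant_window: [0.62, 0.78]
    base_concentration: 3.00
    effect_size: 0.070
  - name: Creatinine
    weight_class: small_molecule
    peaks: [[3.040, 0.6, 0.010], [4.060, 0.4, 0.010]]
    quant_window: [4.03, 4.09]
    base_concentration: 0.09
    effect_size: 0.068
  - name: Citrate
    weight_class: small_molecule
    peaks: [[2.540, 0.5, 0.012], [2.660, 0.5, 0.012]]
    quant_window: [2.50, 2.58]
    base_concentration: 0.11
    effect_size: 0.065
  - name: Lipoproteins CHCH
    weight_class: macromolecule
    peaks: [[5.320, 1.0, 0.250]]
    quant_window: [5.28, 5.40]
    base_concentration: 6.00
    effect_size: 0.051
  - name: Glutamate
    weight_class: small_molecule
    peaks: [[2.340, 1.0, 0.012]]
    quant_window: [2.32, 2.36]
    base_concentration: 0.08
    effect_size: -0.045
  - name: Lipoproteins CH2n
    weight_class: macromolecule
    peaks: [[1.290, 1.0, 0.220]]
    quant_window: [1.24, 1.34]
    base_concentration: 15.00
    effect_size: 0.045
  - name: N,N-Dimethylglycine
    weight_class: small_molecule
    peaks: [[2.920, 1.0, 0.010]]
    quant_window: [2.90, 2.94]
    base_concentration: 0.02
    effect_size: -0.044
  - name: Lipoproteins CHCH2CH
    weight_class: macromolecule
    peaks: [[2.780, 1.0, 0.150]]
    quant_window: [2.72, 2.84]
    base_concentration: 4.00
    effect_size: 0.039
  - name: Lipoproteins CH3
    weight_class: macromolecule
    peaks: [[0.880, 1.0, 0.180]]
    quant_window: [0.82, 0.94]
    base_concentration: 10.00
    effect_size: 0.035
  - name: Pyruvate
    weight_class: small_molecule
    peaks: [[2.380, 1.0, 0.010]]
    quant_window: [2.365, 2.40]
    base_concentration: 0.06
    effect_size: -0.028
  - name: Phenylalanine
    weight_class: small_molecule
    peaks: [[7.330, 0.4, 0.012], [7.380, 0.4, 0.012], [7.430, 0.2, 0.012]]
    quant_window: [7.30, 7.46]
    base_concentration: 0.06
    effect_size: -0.024
  - name: Dimethylsulfone
    weight_class: small_molecule
    peaks: [[3.150, 1.0, 0.008]]
    quant_window: [3.13, 3.17]
    base_concentration: 0.02
    effect_size: -0.018
  - name: Glycine
    weight_class: small_molecule
    peaks: [[3.560, 1.0, 0.008]]
    quant_window: [3.54, 3.58]
    base_concentration: 0.20
    effect_size: -0.012
  - name: Lipoproteins CHCH2CH2
    weight_class: macromolecule
    peaks: [[2.240, 1.0, 0.150]]
    quant_window: [2.18, 2.30]
    base_concentration: 3.00
    effect_size: 0.012
  - name: Creatine
    weight_class: small_molecule
    peaks: [[3.030, 0.6, 0.010], [3.930, 0.4, 0.010]]
    quant_window: [3.91, 3.95]
    base_concentration: 0.04
    effect_size: -0.010
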