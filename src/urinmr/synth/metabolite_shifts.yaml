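# Default urinary metabolite panel for the synthetic cohort generator.
#
# Chemical shifts, multiplicities and scalar couplings are plausible
# literature reference values for urine at pH ~7 (600 MHz); peak areas are
# rough proton-count weights and base concentrations are relative urinary
# abundances in arbitrary units.  group_sign: +1 = elevated in workers,
# -1 = elevated in residents.  Peak fields: [center_ppm, multiplicity,
# J_hz, width_ppm (FWHM), relative_area].
metabolites:
  - name: Leucine
    group_sign: 1
    base_concentration: 1.2
    peaks:
      - [0.96, 2, 6.0, 0.002, 6.0]
      - [1.70, 3, 7.0, 0.002, 3.0]
      - [3.73, 3, 6.0, 0.002, 1.0]
  - name: Isoleucine
    group_sign: -1
    base_concentration: 0.8
    peaks:
      - [0.93, 3, 7.4, 0.002, 3.0]
      - [1.01, 2, 7.0, 0.002, 3.0]
      - [3.66, 2, 4.0, 0.002, 1.0]
  - name: Valine
    group_sign: -1
    base_concentration: 1.0
    peaks:
      - [0.99, 2, 7.0, 0.002, 3.0]
      - [1.04, 2, 7.0, 0.002, 3.0]
      - [2.27, 4, 7.0, 0.002, 1.0]
  - name: Lysine
    group_sign: 1
    base_concentration: 1.0
    peaks:
      - [1.47, 3, 7.5, 0.0025, 2.0]
      - [1.72, 3, 7.5, 0.0025, 2.0]
      - [3.03, 3, 7.5, 0.002, 2.0]
  - name: Tyrosine
    group_sign: 1
    base_concentration: 0.7
    peaks:
      - [6.90, 2, 8.5, 0.002, 2.0]
      - [7.19, 2, 8.5, 0.002, 2.0]
  - name: Tryptophan
    group_sign: -1
    base_concentration: 0.5
    peaks:
      - [7.32, 1, 0.0, 0.002, 1.0]
      - [7.54, 2, 8.0, 0.002, 1.0]
      - [7.73, 2, 8.0, 0.002, 1.0]
  - name: N-acetylglutamine
    group_sign: 1
    base_concentration: 1.5
    peaks:
      - [2.04, 1, 0.0, 0.002, 3.0]
      - [2.33, 3, 7.5, 0.0025, 2.0]
  - name: Acetate
    group_sign: 1
    base_concentration: 1.0
    peaks:
      - [1.92, 1, 0.0, 0.002, 3.0]
  - name: Citrate
    group_sign: -1
    base_concentration: 4.0
    peaks:
      - [2.54, 2, 15.0, 0.0025, 2.0]
      - [2.67, 2, 15.0, 0.0025, 2.0]
  - name: Succinate
    group_sign: -1
    base_concentration: 1.2
    peaks:
      - [2.41, 1, 0.0, 0.002, 4.0]
  - name: 3-Hydroxyisobutyrate
    group_sign: -1
    base_concentration: 0.6
    peaks:
      - [1.07, 2, 7.0, 0.002, 3.0]
      - [3.55, 2, 6.0, 0.002, 1.0]
  - name: Erythro-2,3-dihydroxybutyrate
    group_sign: -1
    base_concentration: 0.5
    peaks:
      - [1.13, 2, 6.5, 0.002, 3.0]
      - [3.87, 2, 6.0, 0.002, 1.0]
  - name: 3-Hydroxy-3-methylbutyrate
    group_sign: -1
    base_concentration: 0.5
    peaks:
      - [1.27, 1, 0.0, 0.002, 6.0]
      - [2.37, 1, 0.0, 0.002, 2.0]
  - name: p-Cresol sulfate
    group_sign: 1
    base_concentration: 1.2
    peaks:
      - [2.31, 1, 0.0, 0.002, 3.0]
      - [7.22, 2, 8.5, 0.002, 2.0]
      - [7.29, 2, 8.5, 0.002, 2.0]
  - name: Creatine
    group_sign: 1
    base_concentration: 1.5
    peaks:
      - [3.04, 1, 0.0, 0.002, 3.0]
      - [3.93, 1, 0.0, 0.002, 2.0]
  - name: Creatinine
    group_sign: -1
    base_concentration: 10.0
    peaks:
      - [3.05, 1, 0.0, 0.002, 3.0]
      - [4.06, 1, 0.0, 0.002, 2.0]
  - name: Unknown pyrimidine
    group_sign: 1
    base_concentration: 0.4
    peaks:
      - [5.80, 2, 8.0, 0.002, 1.0]
      - [7.94, 2, 8.0, 0.002, 1.0]
  - name: Trigonelline
    group_sign: 1
    base_concentration: 0.6
    peaks:
      - [4.44, 1, 0.0, 0.002, 3.0]
      - [8.84, 2, 8.0, 0.002, 2.0]
      - [9.12, 1, 0.0, 0.002, 1.0]
  - name: 4-Hydroxyphenylacetate
    group_sign: -1
    base_concentration: 0.8
    peaks:
      - [3.44, 1, 0.0, 0.002, 2.0]
      - [6.86, 2, 8.5, 0.002, 2.0]
      - [7.16, 2, 8.5, 0.002, 2.0]
  - name: Phenylacetylglycine
    group_sign: -1
    base_concentration: 1.5
    peaks:
      - [3.68, 1, 0.0, 0.002, 2.0]
      - [3.76, 2, 6.0, 0.002, 2.0]
      - [7.42, 3, 7.5, 0.002, 5.0]
  - name: Hippurate
    group_sign: -1
    base_concentration: 5.0
    peaks:
      - [3.97, 2, 6.0, 0.002, 2.0]
      - [7.55, 3, 7.7, 0.002, 2.0]
      - [7.64, 3, 7.4, 0.002, 1.0]
      - [7.83, 2, 7.7, 0.002, 2.0]
  - name: Pyroglutamate
    group_sign: -1
    base_concentration: 1.0
    peaks:
      - [2.02, 3, 8.0, 0.0025, 1.0]
      - [2.50, 3, 8.0, 0.0025, 2.0]
      - [4.17, 2, 7.0, 0.002, 1.0]
  - name: Taurine
    group_sign: -1
    base_concentration: 2.0
    peaks:
      - [3.26, 3, 6.6, 0.002, 2.0]
      - [3.42, 3, 6.6, 0.002, 2.0]
  - name: 1-Methylnicotinamide
    group_sign: -1
    base_concentration: 0.5
    peaks:
      - [4.48, 1, 0.0, 0.002, 3.0]
      - [8.90, 2, 8.0, 0.002, 1.0]
      - [9.28, 1, 0.0, 0.002, 1.0]
  - name: Furoylglycine
    group_sign: -1
    base_concentration: 0.7
    peaks:
      - [3.92, 2, 6.0, 0.002, 2.0]
      - [6.63, 2, 3.5, 0.002, 1.0]
      - [7.68, 1, 0.0, 0.002, 1.0]
  - name: 4-Hydroxybenzoate
    group_sign: -1
    base_concentration: 0.4
    peaks:
      - [6.92, 2, 8.7, 0.002, 2.0]
      - [7.87, 2, 8.7, 0.002, 2.0]
  - name: Pseudouridine
    group_sign: -1
    base_concentration: 0.6
    peaks:
      - [4.28, 2, 5.0, 0.002, 1.0]
      - [7.67, 1, 0.0, 0.002, 1.0]
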