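# Default per-population allele frequencies for the synthetic cohort
# simulator. Each value is the frequency of the FIRST (alphabetically
# earlier) allele of the panel pair:
#   rs12913832 A/G -> freq of A      rs885479   A/G -> freq of A
#   rs1545397  A/T -> freq of A      rs6119471  C/G -> freq of C
#   rs16891982 C/G -> freq of C      rs12203592 C/T -> freq of C
#   rs1426654  A/G -> freq of A      rs12896399 G/T -> freq of G
#
# SYNTHETIC DEFAULTS: these are hand-picked to produce qualitatively
# population-like rule behaviour (e.g. high skin call rate for "E"); they
# are NOT estimates from any study cohort.
population_mix:
  AA: 0.05
  SA: 0.04
  EA: 0.04
  E: 0.62
  mix: 0.25
allele_freqs:
  E:
    rs12913832: 0.20
    rs1545397: 0.85
    rs16891982: 0.05
    rs1426654: 0.98
    rs885479: 0.10
    rs6119471: 0.95
    rs12203592: 0.85
    rs12896399: 0.55
  AA:
    rs12913832: 0.95
    rs1545397: 0.90
    rs16891982: 0.85
    rs1426654: 0.10
    rs885479: 0.05
    rs6119471: 0.35
    rs12203592: 0.98
    rs12896399: 0.90
  SA:
    rs12913832: 0.90
    rs1545397: 0.80
    rs16891982: 0.70
    rs1426654: 0.70
    rs885479: 0.15
    rs6119471: 0.95
    rs12203592: 0.95
    rs12896399: 0.75
  EA:
    rs12913832: 0.99
    rs1545397: 0.30
    rs16891982: 0.95
    rs1426654: 0.05
    rs885479: 0.70
    rs6119471: 0.90
    rs12203592: 0.99
    rs12896399: 0.60
  mix:
    rs12913832: 0.50
    rs1545397: 0.50
    rs16891982: 0.50
    rs1426654: 0.50
    rs885479: 0.50
    rs6119471: 0.50
    rs12203592: 0.50
    rs12896399: 0.50
discordance_rate: 0.0
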