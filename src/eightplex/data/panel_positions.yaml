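# Fallback (chrom, pos) -> rsID lookup for VCF records with an empty ID
# column. Matching by rsID always takes precedence; these coordinates are
# 1-based GRCh38 and should be overridden (eightplex predict --positions)
# if your VCF uses another build or if exact positional matching matters.
build: GRCh38
positions:
  rs12913832: {chrom: "15", pos: 28120472}
  rs1545397: {chrom: "15", pos: 27754874}
  rs16891982: {chrom: "5", pos: 33951588}
  rs1426654: {chrom: "15", pos: 48134287}
  rs885479: {chrom: "16", pos: 89986154}
  rs6119471: {chrom: "20", pos: 34202585}
  rs12203592: {chrom: "6", pos: 396321}
  rs12896399: {chrom: "14", pos: 92307319}
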