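"""Homozygote-elimination skin-color prediction.

Five homozygous genotypes mark lighter skin (rs12913832 G/G, rs16891982
G/G, rs1426654 A/A, rs1545397 T/T, rs885479 A/A) and one marks darker skin
(rs6119471 G/G). At least two light markers predict *not dark*; the
stricter combination rs12913832 G/G + rs16891982 G/G + rs1426654 A/A
predicts *light*; the dark marker alone predicts *not light*. Only
homozygous genotypes are informative, so samples without enough of them
are *inconclusive*; a sample carrying both light- and dark-branch signals
is flagged *conflict* rather than silently resolved.
"""

from __future__ import annotations

from dataclasses import dataclass

from .panel import SampleGenotypes

__all__ = ["SkinPrediction", "predict_skin", "SKIN_LABELS", "LIGHT_MARKERS", "DARK_MARKER"]

SKIN_LABELS = ("light", "not_dark", "not_light", "inconclusive", "conflict")

#: (rsid, homozygous genotype) pairs associated with lighter skin
LIGHT_MARKERS = (
    ("rs12913832", ("G", "G")),
    ("rs16891982", ("G", "G")),
    ("rs1426654", ("A", "A")),
    ("rs1545397", ("T", "T")),
    ("rs885479", ("A", "A")),
)

#: the three markers that must all hold for the strict "light" call
_LIGHT_CORE = LIGHT_MARKERS[:3]

DARK_MARKER = ("rs6119471", ("G", "G"))


@dataclass(frozen=True)
class SkinPrediction:
    label: str
    fired_rules: tuple[str, ...] = ()
    light_marker_count: int = 0


def predict_skin(s: SampleGenotypes) -> SkinPrediction:
    """Predict skin color for one sample. Missing genotypes never satisfy
    a marker condition; no imputation is attempted."""
    held = [
        (rsid, gt)
        for rsid, gt in LIGHT_MARKERS
        if s.genotype(rsid) == gt
    ]
    n_light = len(held)
    light_core = all(s.genotype(rsid) == gt for rsid, gt in _LIGHT_CORE)
    dark = s.genotype(DARK_MARKER[0]) == DARK_MARKER[1]

    lighter_rule: str | None = None
    if light_core:
        lighter_rule = "light/" + "+".join(f"{r}={g[0]}{g[1]}" for r, g in _LIGHT_CORE)
    elif n_light >= 2:
        lighter_rule = "not_dark/" + "+".join(f"{r}={g[0]}{g[1]}" for r, g in held)
    dark_rule = "not_light/rs6119471=GG" if dark else None

    if lighter_rule and dark_rule:
        return SkinPrediction(
            label="conflict",
            fired_rules=(lighter_rule, dark_rule),
            light_marker_count=n_light,
        )
    if light_core:
        return SkinPrediction("light", (lighter_rule,), n_light)
    if n_light >= 2:
        return SkinPrediction("not_dark", (lighter_rule,), n_light)
    if dark:
        return SkinPrediction("not_light", (dark_rule,), n_light)
    return SkinPrediction("inconclusive", (), n_light)
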