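"""Two-step rule-based eye-color prediction.

Step 1 anchors on rs12913832: A/A or A/G gives the baseline *not blue*
(brown or green), G/G gives *not brown* (green or blue). Homozygous
genotypes at rs6119471, rs16891982, and rs12203592 can refine the baseline
to a positive color (brown, green, or blue). Step 2 re-examines samples
left with only a negative description: rs12913832 homozygotes can be
upgraded to blue (G/G plus rs12896399 T/T) or brown (A/A plus rs12896399
G/G). The legacy ``7plex`` mode stops after step 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .panel import EYE_SNPS, SampleGenotypes

__all__ = ["EyePrediction", "predict_eye", "predict_eye_step1", "EYE_LABELS", "MODES"]

EYE_LABELS = ("brown", "green", "blue", "not_blue", "not_brown", "no_call")
POSITIVE_EYE_LABELS = ("brown", "green", "blue")
MODES = ("8plex", "7plex")

#: resolution order when several positive step-1 rules fire at once
_PRECEDENCE = ("brown", "green", "blue")


@dataclass(frozen=True)
class EyePrediction:
    label: str
    step: int = 1
    fired_rules: tuple[str, ...] = ()
    conflict: bool = False
    notes: tuple[str, ...] = ()

    @property
    def is_positive(self) -> bool:
        return self.label in POSITIVE_EYE_LABELS


def _gt(s: SampleGenotypes, rsid: str) -> tuple[str, str] | None:
    return s.genotype(rsid)


def predict_eye_step1(s: SampleGenotypes) -> EyePrediction:
    """Apply the step-1 rules only (baseline plus positive refinements)."""
    g832 = _gt(s, "rs12913832")
    if g832 is None:
        return EyePrediction(label="no_call", fired_rules=(), notes=("rs12913832 missing",))

    if g832 == ("G", "G"):
        baseline = "not_brown"
    else:  # ("A", "A") or ("A", "G")
        baseline = "not_blue"

    g982 = _gt(s, "rs16891982")
    g471 = _gt(s, "rs6119471")
    g592 = _gt(s, "rs12203592")

    fired: list[tuple[str, str]] = []  # (label, rule id)
    if baseline == "not_blue":
        if g471 == ("G", "G"):
            fired.append(("brown", "brown/rs6119471=GG"))
        if g982 == ("C", "C"):
            fired.append(("brown", "brown/rs16891982=CC"))
    if g832 == ("G", "G") and g982 == ("C", "C"):
        fired.append(("green", "green/rs12913832=GG+rs16891982=CC"))
    if g832 == ("A", "G") and g592 == ("T", "T"):
        fired.append(("green", "green/rs12913832=AG+rs12203592=TT"))
    if g832 == ("G", "G") and g592 == ("T", "T"):
        fired.append(("blue", "blue/rs12913832=GG+rs12203592=TT"))

    notes = tuple(
        f"{rsid} missing"
        for rsid, g in (("rs16891982", g982), ("rs6119471", g471), ("rs12203592", g592))
        if g is None
    )

    if not fired:
        return EyePrediction(label=baseline, fired_rules=(), notes=notes)

    labels = {lab for lab, _ in fired}
    winner = next(lab for lab in _PRECEDENCE if lab in labels)
    return EyePrediction(
        label=winner,
        step=1,
        fired_rules=tuple(rule for _, rule in fired),
        conflict=len(labels) > 1,
        notes=notes,
    )


def predict_eye(s: SampleGenotypes, mode: str = "8plex") -> EyePrediction:
    """Full eye-color prediction.

    ``8plex`` runs both steps; ``7plex`` returns the step-1 result
    unchanged. Step 2 only ever upgrades a negative description and never
    fires for rs12913832 heterozygotes.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    step1 = predict_eye_step1(s)
    if mode == "7plex" or step1.is_positive or step1.label == "no_call":
        return step1

    g832 = _gt(s, "rs12913832")
    g399 = _gt(s, "rs12896399")
    if g832 == ("G", "G") and g399 == ("T", "T"):
        return EyePrediction(
            label="blue",
            step=2,
            fired_rules=step1.fired_rules + ("blue/rs12913832=GG+rs12896399=TT",),
            conflict=step1.conflict,
            notes=step1.notes,
        )
    if g832 == ("A", "A") and g399 == ("G", "G"):
        return EyePrediction(
            label="brown",
            step=2,
            fired_rules=step1.fired_rules + ("brown/rs12913832=AA+rs12896399=GG",),
            conflict=step1.conflict,
            notes=step1.notes,
        )
    notes = step1.notes
    if g399 is None:
        notes = notes + ("rs12896399 missing",)
    return EyePrediction(
        label=step1.label,
        step=1,
        fired_rules=step1.fired_rules,
        conflict=step1.conflict,
        notes=notes,
    )
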