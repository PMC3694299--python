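"""Evaluation semantics, packaged outcome-table fixtures, and derived rates.

An *error* is a predicted color incompatible with the independently binned
actual color. Negative descriptions (not blue, not brown, not dark, not
light) are compatible with two bins each and only count as errors when they
exclude the true bin. Non-calls (``no_call``, ``inconclusive``,
``conflict``) never count as errors.

The package ships transcriptions of the reference training/test outcome
tables as fixtures; :func:`summarize_fixture` reduces them to the summary
counts and :func:`fixture_rates` to the derived percentage rates, each
labeled with the denominator convention it uses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

import pandas as pd

try:
    from importlib.resources import files as _resource_files
except ImportError:  # pragma: no cover
    from importlib_resources import files as _resource_files

from .eye import POSITIVE_EYE_LABELS, EyePrediction
from .panel import EYE_BINS, SKIN_BINS, PhenotypeRecord
from .skin import SkinPrediction
from .stats import StatResult, two_proportion_z

__all__ = [
    "PredictionFixtureRow",
    "EvaluationSummary",
    "EvaluationError",
    "TargetResult",
    "is_compatible",
    "builtin_fixture",
    "summarize_fixture",
    "fixture_rates",
    "evaluate_cohort",
    "positive_description_gain",
    "verify_targets",
    "REFERENCE_TARGETS",
]

#: predicted label → set of truth bins it is compatible with
COMPATIBILITY: dict[str, frozenset[str]] = {
    "brown": frozenset({"brown"}),
    "green": frozenset({"green"}),
    "blue": frozenset({"blue"}),
    "not_blue": frozenset({"brown", "green"}),
    "not_brown": frozenset({"green", "blue"}),
    "light": frozenset({"light"}),
    "not_dark": frozenset({"light", "medium"}),
    "not_light": frozenset({"medium", "dark"}),
}

#: labels that are non-calls: compatible with everything, never errors
NON_CALLS = frozenset({"no_call", "inconclusive", "conflict"})

_ALL_BINS = frozenset(EYE_BINS) | frozenset(SKIN_BINS)


class EvaluationError(ValueError):
    pass


def is_compatible(predicted: str, actual: str) -> bool:
    """True iff ``predicted`` is not an error against the truth bin ``actual``."""
    if actual not in _ALL_BINS:
        raise EvaluationError(f"unknown phenotype bin {actual!r}")
    if predicted in NON_CALLS:
        return True
    try:
        return actual in COMPATIBILITY[predicted]
    except KeyError:
        raise EvaluationError(f"unknown prediction label {predicted!r}") from None


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PredictionFixtureRow:
    """One line of an outcome table: a (population, truth-bin, predicted-label)
    cell with its count, error count, nested step-2 refinements (eye only),
    and the inconclusive count attached to its group (skin only)."""

    dataset: str
    trait: str
    population: str
    bin: str
    step1_label: str | None
    step1_count: int
    step1_errors: int
    step2_entries: tuple[tuple[str, int, int], ...] = ()
    inconclusive_count: int = 0

    def __post_init__(self) -> None:
        if self.step1_errors > self.step1_count:
            raise EvaluationError(
                f"fixture row {self.population}/{self.bin}: errors exceed count"
            )
        if sum(c for _, c, _ in self.step2_entries) > self.step1_count:
            raise EvaluationError(
                f"fixture row {self.population}/{self.bin}: step-2 counts exceed parent"
            )


def _load_fixture_table() -> list[PredictionFixtureRow]:
    text = (_resource_files("eightplex") / "data" / "table_fixtures.tsv").read_text()
    rows: list[PredictionFixtureRow] = []
    lines = text.strip().split("\n")
    header = lines[0].split("\t")
    for line in lines[1:]:
        rec = dict(zip(header, line.split("\t")))
        step2: tuple[tuple[str, int, int], ...] = ()
        if rec["step2"] != ".":
            step2 = tuple(
                (lab, int(cnt), int(err))
                for lab, cnt, err in (e.split(":") for e in rec["step2"].split(";"))
            )
        rows.append(
            PredictionFixtureRow(
                dataset=rec["dataset"],
                trait=rec["trait"],
                population=rec["population"],
                bin=rec["bin"],
                step1_label=None if rec["step1_label"] == "." else rec["step1_label"],
                step1_count=int(rec["step1_count"]),
                step1_errors=int(rec["step1_errors"]),
                step2_entries=step2,
                inconclusive_count=int(rec["inconclusive"]),
            )
        )
    return rows


def builtin_fixture(dataset: str, trait: str) -> list[PredictionFixtureRow]:
    """Return the packaged outcome-table fixture for one (dataset, trait)."""
    if dataset not in ("training", "test") or trait not in ("eye", "skin"):
        raise EvaluationError(f"unknown fixture ({dataset!r}, {trait!r})")
    return [
        r for r in _load_fixture_table() if r.dataset == dataset and r.trait == trait
    ]


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

@dataclass
class EvaluationSummary:
    trait: str
    n_samples: int = 0
    n_called: int = 0
    n_no_call: int = 0
    n_positive_step1: int = 0
    n_positive_step2: int = 0
    n_errors_step1: int = 0
    n_errors_step2: int = 0
    per_population: dict[str, "EvaluationSummary"] = field(default_factory=dict)

    @property
    def n_positive_total(self) -> int:
        return self.n_positive_step1 + self.n_positive_step2

    @property
    def n_errors_total(self) -> int:
        return self.n_errors_step1 + self.n_errors_step2

    @property
    def call_rate(self) -> float:
        return self.n_called / self.n_samples if self.n_samples else 0.0


def _positive(trait: str, label: str | None) -> bool:
    if label is None:
        return False
    return label in POSITIVE_EYE_LABELS if trait == "eye" else label == "light"


def summarize_fixture(rows: Iterable[PredictionFixtureRow]) -> EvaluationSummary:
    """Reduce one fixture to its summary counts, overall and per population."""
    rows = list(rows)
    if not rows:
        raise EvaluationError("empty fixture")
    keys = {(r.dataset, r.trait) for r in rows}
    if len(keys) > 1:
        raise EvaluationError(f"mixed fixtures passed to summarize_fixture: {keys}")
    trait = rows[0].trait

    total = EvaluationSummary(trait=trait)
    for r in rows:
        for summary in (total, total.per_population.setdefault(
            r.population, EvaluationSummary(trait=trait)
        )):
            summary.n_samples += r.step1_count + r.inconclusive_count
            summary.n_called += r.step1_count
            summary.n_no_call += r.inconclusive_count
            summary.n_errors_step1 += r.step1_errors
            if _positive(trait, r.step1_label):
                summary.n_positive_step1 += r.step1_count
            for label, count, errors in r.step2_entries:
                summary.n_errors_step2 += errors
                if _positive(trait, label):
                    summary.n_positive_step2 += count
    return total


def _half_up(x: float, ndigits: int) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _truncate(x: float, ndigits: int) -> float:
    factor = 10**ndigits
    return int(x * factor) / factor


def fixture_rates(dataset: str, trait: str) -> dict[str, float]:
    """Derived percentage rates for one fixture, under the conventions the
    reference summaries use.

    Eye error rates are computed over the European subset only (the subset
    with full eye-color variation). Step-1 rates use all European samples
    as denominator; test-set step-2 and overall rates use the European
    samples *not* positively described in step 1. Step rates are rounded
    half-up; the overall test rate is truncated to two decimals (the
    reporting convention of the source summaries).
    """
    summary = summarize_fixture(builtin_fixture(dataset, trait))
    eur = summary.per_population["E"]
    rates: dict[str, float] = {}
    if trait == "eye":
        rates["n_positive_step1"] = summary.n_positive_step1
        rates["n_positive_step2"] = summary.n_positive_step2
        rates["n_positive_total"] = summary.n_positive_total
        rates["positive_gain_pct_of_all"] = _half_up(
            100 * summary.n_positive_step2 / summary.n_samples, 0
        )
        if dataset == "training":
            rates["european_step1_error_rate_pct"] = _half_up(
                100 * eur.n_errors_step1 / eur.n_samples, 0
            )
            rates["european_step2_error_rate_pct"] = _half_up(
                100 * eur.n_errors_step2 / eur.n_samples, 0
            )
        else:
            remaining = eur.n_samples - eur.n_positive_step1
            rates["european_step1_error_rate_pct"] = _half_up(
                100 * eur.n_errors_step1 / eur.n_samples, 2
            )
            rates["european_step2_error_rate_pct"] = _half_up(
                100 * eur.n_errors_step2 / remaining, 2
            )
            rates["european_overall_error_rate_pct"] = _truncate(
                100 * eur.n_errors_total / remaining, 2
            )
    else:
        rates["n_predictions"] = summary.n_called
        rates["n_light"] = summary.n_positive_step1
        rates["n_errors"] = summary.n_errors_total
        rates["n_inconclusive"] = summary.n_no_call
        rates["call_rate_pct"] = _half_up(100 * summary.call_rate, 0)
        rates["error_rate_pct"] = _half_up(
            100 * summary.n_errors_total / summary.n_called, 0
        )
        rates["european_call_rate_pct"] = _half_up(100 * eur.call_rate, 0)
    return rates


# ---------------------------------------------------------------------------
# cohort evaluation
# ---------------------------------------------------------------------------

def evaluate_cohort(
    eye_predictions: Mapping[str, EyePrediction] | None,
    skin_predictions: Mapping[str, SkinPrediction] | None,
    truths: Iterable[PhenotypeRecord],
) -> dict[str, EvaluationSummary]:
    """Score predictions against binned truth, per trait and per population.

    Every prediction must have a matching truth record (and vice versa, for
    each trait supplied). Samples whose truth bin is absent for a trait are
    skipped for that trait. Eye errors are attributed to the step at which
    the final label was produced.
    """
    truth_by_id = {t.sample_id: t for t in truths}
    out: dict[str, EvaluationSummary] = {}

    for trait, predictions in (("eye", eye_predictions), ("skin", skin_predictions)):
        if predictions is None:
            continue
        missing = set(predictions) ^ set(truth_by_id)
        if missing:
            raise EvaluationError(
                f"{trait}: sample ids do not align; mismatched ids {sorted(missing)[:5]}"
            )
        summary = EvaluationSummary(trait=trait)
        for sid, pred in predictions.items():
            truth = truth_by_id[sid]
            actual = truth.eye_bin if trait == "eye" else truth.skin_bin
            if actual is None:
                continue
            pop = summary.per_population.setdefault(
                truth.population, EvaluationSummary(trait=trait)
            )
            step = getattr(pred, "step", 1)
            for s in (summary, pop):
                s.n_samples += 1
                if pred.label in NON_CALLS:
                    s.n_no_call += 1
                    continue
                s.n_called += 1
                if _positive(trait, pred.label):
                    if step == 2:
                        s.n_positive_step2 += 1
                    else:
                        s.n_positive_step1 += 1
                if not is_compatible(pred.label, actual):
                    if step == 2:
                        s.n_errors_step2 += 1
                    else:
                        s.n_errors_step1 += 1
        out[trait] = summary
    return out


def positive_description_gain(x1: int, n1: int, x2: int, n2: int) -> StatResult:
    """Pooled two-proportion z-test for a change in positive-description
    counts (delegates to :func:`eightplex.stats.two_proportion_z`)."""
    return two_proportion_z(x1, n1, x2, n2)


# ---------------------------------------------------------------------------
# reference targets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TargetResult:
    target_id: str
    description: str
    value: float
    expected: float
    cmp: str  # "eq" or "le"
    n: int

    @property
    def passed(self) -> bool:
        if self.cmp == "eq":
            return self.value == self.expected
        return self.value <= self.expected


#: reference values for the packaged fixtures: (description, expected, cmp)
REFERENCE_TARGETS: dict[str, tuple[str, float, str]] = {
    "t1": ("training eye: total positive descriptions (steps 1+2)", 248, "eq"),
    "t2": ("training eye: European step-1 error rate, % (nearest integer)", 2, "eq"),
    "t3": ("test eye: step-1 positive descriptions", 56, "eq"),
    "t4": ("test eye: European step-1 error rate, % (2 decimals)", 1.75, "eq"),
    "t5": ("test eye: European step-2 error rate, % (2 decimals)", 2.73, "eq"),
    "t6": ("test eye: European overall error rate, % (must not exceed)", 5.0, "le"),
    "t7": ("training skin: predictions made (non-inconclusive)", 600, "eq"),
    "t8": ("training skin: positive (light) predictions", 255, "eq"),
    "t9": ("test skin: predictions made (non-inconclusive)", 131, "eq"),
    "t10": ("test skin: positive (light) predictions", 63, "eq"),
    "t11": ("test skin: European call rate, % (nearest integer)", 94, "eq"),
    "t12": ("test eye: total positive descriptions (steps 1+2)", 86, "eq"),
}


def compute_target(target_id: str) -> tuple[float, int]:
    """Recompute one reference target from the packaged fixtures.

    Returns (value, n) where n is the cohort size the value is computed
    over.
    """
    eye_tr = summarize_fixture(builtin_fixture("training", "eye"))
    if target_id == "t1":
        return eye_tr.n_positive_total, eye_tr.n_samples
    if target_id == "t2":
        return fixture_rates("training", "eye")["european_step1_error_rate_pct"], 555
    eye_te = summarize_fixture(builtin_fixture("test", "eye"))
    if target_id == "t3":
        return eye_te.n_positive_step1, eye_te.n_samples
    if target_id == "t4":
        return fixture_rates("test", "eye")["european_step1_error_rate_pct"], 114
    if target_id == "t5":
        return fixture_rates("test", "eye")["european_step2_error_rate_pct"], 110
    if target_id == "t6":
        return fixture_rates("test", "eye")["european_overall_error_rate_pct"], 110
    if target_id == "t7":
        return summarize_fixture(builtin_fixture("training", "skin")).n_called, 803
    if target_id == "t8":
        return fixture_rates("training", "skin")["n_light"], 803
    if target_id == "t9":
        return summarize_fixture(builtin_fixture("test", "skin")).n_called, 212
    if target_id == "t10":
        return fixture_rates("test", "skin")["n_light"], 212
    if target_id == "t11":
        return fixture_rates("test", "skin")["european_call_rate_pct"], 114
    if target_id == "t12":
        return eye_te.n_positive_total, eye_te.n_samples
    raise EvaluationError(f"unknown target id {target_id!r}")


def verify_targets() -> list[TargetResult]:
    """Recompute every reference target from the fixtures and compare it to
    the stored expectation."""
    results = []
    for tid, (desc, expected, cmp) in REFERENCE_TARGETS.items():
        value, n = compute_target(tid)
        results.append(
            TargetResult(
                target_id=tid, description=desc, value=value,
                expected=expected, cmp=cmp, n=n,
            )
        )
    return results
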