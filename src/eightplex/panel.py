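"""Panel definition and genotype/phenotype input handling.

The panel consists of eight biallelic SNPs. Five are used for eye-color
prediction, six for skin-color prediction, and three are shared between the
two traits. Genotypes are stored as unordered allele pairs (phase is never
used by the decision rules) and all input routes — VCF or a simple
tab-separated genotype table — funnel through :func:`normalize_genotype`,
which enforces the panel allele conventions and handles strand flips for
non-ambiguous sites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

try:  # pragma: no cover - import guard exercised implicitly
    from importlib.resources import files as _resource_files
except ImportError:  # pragma: no cover
    from importlib_resources import files as _resource_files

__all__ = [
    "SnpDef",
    "GenotypeCall",
    "SampleGenotypes",
    "PhenotypeRecord",
    "PanelValidationError",
    "VcfParseError",
    "StrandFlipWarning",
    "EYE_SNPS",
    "SKIN_SNPS",
    "POPULATIONS",
    "EYE_BINS",
    "SKIN_BINS",
    "MISSING_TOKENS",
    "panel",
    "panel_rsids",
    "get_snp",
    "normalize_genotype",
    "read_vcf",
    "read_genotype_table",
    "write_genotype_table",
    "read_phenotype_table",
    "write_phenotype_table",
    "default_positions",
]

#: population codes used throughout reports and fixtures
POPULATIONS = ("AA", "SA", "EA", "E", "mix")

EYE_BINS = ("blue", "green", "brown")
SKIN_BINS = ("light", "medium", "dark")

#: input tokens treated as a missing genotype
MISSING_TOKENS = frozenset({"NA", ".", "./.", ".|.", ""})

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_BASES = frozenset("ACGT")


class PanelValidationError(ValueError):
    """An allele or token is irreconcilable with the panel definition."""


class VcfParseError(ValueError):
    """The VCF input could not be parsed."""


class StrandFlipWarning(UserWarning):
    """Raised (as a warning) when a genotype is rescued by complementation."""


@dataclass(frozen=True)
class SnpDef:
    """One panel SNP: identity, canonical alleles, and trait assignment."""

    rsid: str
    gene: str
    alleles: tuple[str, str]  # alphabetical; frequencies refer to alleles[0]
    used_for_eye: bool
    used_for_skin: bool

    @property
    def strand_ambiguous(self) -> bool:
        """True iff the allele pair is its own reverse complement (C/G, A/T)."""
        a, b = self.alleles
        return _COMPLEMENT[a] == b

    def __post_init__(self) -> None:
        a, b = self.alleles
        if a == b or not {a, b} <= _BASES:
            raise PanelValidationError(
                f"{self.rsid}: allele pair must be two distinct bases, got {self.alleles}"
            )


@dataclass(frozen=True)
class GenotypeCall:
    """An unordered diploid call at one rsID; ``alleles is None`` == MISSING."""

    rsid: str
    alleles: tuple[str, str] | None

    @property
    def is_missing(self) -> bool:
        return self.alleles is None

    @staticmethod
    def missing(rsid: str) -> "GenotypeCall":
        return GenotypeCall(rsid, None)


@dataclass
class SampleGenotypes:
    """All panel calls for one donor, keyed by rsID."""

    sample_id: str
    calls: dict[str, GenotypeCall] = field(default_factory=dict)

    def genotype(self, rsid: str) -> tuple[str, str] | None:
        """Unordered allele pair at ``rsid``, or None if uncalled/missing."""
        call = self.calls.get(rsid)
        return None if call is None else call.alleles


@dataclass(frozen=True)
class PhenotypeRecord:
    """Binned ground truth for one donor."""

    sample_id: str
    population: str
    eye_bin: str | None = None
    skin_bin: str | None = None

    def __post_init__(self) -> None:
        if self.population not in POPULATIONS:
            raise PanelValidationError(
                f"{self.sample_id}: unknown population {self.population!r}; "
                f"expected one of {POPULATIONS}"
            )
        if self.eye_bin is not None and self.eye_bin not in EYE_BINS:
            raise PanelValidationError(
                f"{self.sample_id}: unknown eye bin {self.eye_bin!r}"
            )
        if self.skin_bin is not None and self.skin_bin not in SKIN_BINS:
            raise PanelValidationError(
                f"{self.sample_id}: unknown skin bin {self.skin_bin!r}"
            )


_PANEL: tuple[SnpDef, ...] = (
    SnpDef("rs12913832", "HERC2", ("A", "G"), used_for_eye=True, used_for_skin=True),
    SnpDef("rs1545397", "OCA2", ("A", "T"), used_for_eye=False, used_for_skin=True),
    SnpDef("rs16891982", "SLC45A2", ("C", "G"), used_for_eye=True, used_for_skin=True),
    SnpDef("rs1426654", "SLC24A5", ("A", "G"), used_for_eye=False, used_for_skin=True),
    SnpDef("rs885479", "MC1R", ("A", "G"), used_for_eye=False, used_for_skin=True),
    SnpDef("rs6119471", "ASIP", ("C", "G"), used_for_eye=True, used_for_skin=True),
    SnpDef("rs12203592", "IRF4", ("C", "T"), used_for_eye=True, used_for_skin=False),
    SnpDef("rs12896399", "SLC24A4", ("G", "T"), used_for_eye=True, used_for_skin=False),
)

_PANEL_BY_RSID: dict[str, SnpDef] = {s.rsid: s for s in _PANEL}

EYE_SNPS = tuple(s.rsid for s in _PANEL if s.used_for_eye)
SKIN_SNPS = tuple(s.rsid for s in _PANEL if s.used_for_skin)


def panel() -> tuple[SnpDef, ...]:
    """Return the immutable 8-SNP panel definition."""
    return _PANEL


def panel_rsids() -> tuple[str, ...]:
    return tuple(s.rsid for s in _PANEL)


def get_snp(rsid: str) -> SnpDef:
    try:
        return _PANEL_BY_RSID[rsid]
    except KeyError:
        raise PanelValidationError(f"{rsid!r} is not a panel SNP") from None


def normalize_genotype(raw: Sequence[str], snp: SnpDef) -> GenotypeCall:
    """Validate a raw allele pair against a panel SNP.

    Alleles already inside the canonical pair are accepted as-is. For
    non-strand-ambiguous SNPs, a pair that only fits after base
    complementation is complemented and a :class:`StrandFlipWarning` is
    emitted. Strand-ambiguous SNPs (C/G, A/T) are never flipped — a
    mismatching pair there is an error, because a silent flip could not be
    detected from allele labels.

    The operation is idempotent: its output always validates unchanged.
    """
    a, b = raw
    a, b = a.upper(), b.upper()
    if not {a, b} <= _BASES:
        raise PanelValidationError(
            f"{snp.rsid}: invalid allele token in {tuple(raw)!r}"
        )
    pair = tuple(sorted((a, b)))
    allowed = set(snp.alleles)
    if set(pair) <= allowed:
        return GenotypeCall(snp.rsid, pair)
    flipped = tuple(sorted((_COMPLEMENT[a], _COMPLEMENT[b])))
    if set(flipped) <= allowed:
        if snp.strand_ambiguous:
            # unreachable for a C/G or A/T pair (complement maps onto itself),
            # but kept as an explicit guard against panel edits
            raise PanelValidationError(
                f"{snp.rsid}: refusing to strand-flip an ambiguous SNP"
            )
        warnings.warn(
            f"{snp.rsid}: alleles {pair} complemented to {flipped} "
            f"(opposite-strand input assumed)",
            StrandFlipWarning,
            stacklevel=2,
        )
        return GenotypeCall(snp.rsid, flipped)
    raise PanelValidationError(
        f"{snp.rsid}: alleles {pair} irreconcilable with panel pair {snp.alleles}"
    )


def _complete_sample(sample: SampleGenotypes) -> SampleGenotypes:
    """Fill uncalled panel sites with MISSING so every sample has 8 keys."""
    for rsid in panel_rsids():
        sample.calls.setdefault(rsid, GenotypeCall.missing(rsid))
    return sample


# ---------------------------------------------------------------------------
# genotype TSV dialect
# ---------------------------------------------------------------------------

def read_genotype_table(path: str | Path) -> list[SampleGenotypes]:
    """Read the genotype TSV dialect (sample_id column + one column per rsID).

    Cells are ``A/G``-style unordered pairs or a missing token (``NA``, ``.``,
    ``./.``). Allele order within a cell is irrelevant.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "sample_id" not in df.columns:
        raise PanelValidationError(f"{path}: missing required column 'sample_id'")
    rs_cols = [c for c in df.columns if c != "sample_id"]
    unknown = [c for c in rs_cols if c not in _PANEL_BY_RSID]
    if unknown:
        raise PanelValidationError(f"{path}: unknown rsID column(s) {unknown}")
    samples = []
    for _, row in df.iterrows():
        sid = row["sample_id"]
        s = SampleGenotypes(sample_id=sid)
        for rsid in rs_cols:
            cell = row[rsid].strip()
            if cell in MISSING_TOKENS:
                s.calls[rsid] = GenotypeCall.missing(rsid)
                continue
            parts = cell.replace("|", "/").split("/")
            if len(parts) != 2 or not all(parts):
                raise PanelValidationError(
                    f"{path}: sample {sid!r}, column {rsid}: "
                    f"cannot parse genotype cell {cell!r}"
                )
            try:
                s.calls[rsid] = normalize_genotype(parts, _PANEL_BY_RSID[rsid])
            except PanelValidationError as exc:
                raise PanelValidationError(
                    f"{path}: sample {sid!r}: {exc}"
                ) from exc
        samples.append(_complete_sample(s))
    return samples


def write_genotype_table(samples: Iterable[SampleGenotypes], path: str | Path) -> None:
    """Write samples in the genotype TSV dialect (all 8 panel columns)."""
    rsids = panel_rsids()
    with open(path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(rsids) + "\n")
        for s in samples:
            cells = []
            for rsid in rsids:
                gt = s.genotype(rsid)
                cells.append("NA" if gt is None else f"{gt[0]}/{gt[1]}")
            fh.write(s.sample_id + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# phenotype TSV
# ---------------------------------------------------------------------------

def read_phenotype_table(path: str | Path) -> list[PhenotypeRecord]:
    """Read phenotype records (sample_id, population, eye_bin, skin_bin)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"sample_id", "population"}
    if not required <= set(df.columns):
        raise PanelValidationError(
            f"{path}: phenotype table needs columns {sorted(required)}"
        )
    records = []
    for i, row in df.iterrows():
        eye = row.get("eye_bin", "").strip() if "eye_bin" in df.columns else ""
        skin = row.get("skin_bin", "").strip() if "skin_bin" in df.columns else ""
        try:
            records.append(
                PhenotypeRecord(
                    sample_id=row["sample_id"],
                    population=row["population"].strip(),
                    eye_bin=eye or None,
                    skin_bin=skin or None,
                )
            )
        except PanelValidationError as exc:
            raise PanelValidationError(f"{path}: row {i + 2}: {exc}") from exc
    return records


def write_phenotype_table(records: Iterable[PhenotypeRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tpopulation\teye_bin\tskin_bin\n")
        for r in records:
            fh.write(
                f"{r.sample_id}\t{r.population}\t{r.eye_bin or ''}\t{r.skin_bin or ''}\n"
            )


# ---------------------------------------------------------------------------
# VCF input
# ---------------------------------------------------------------------------

def default_positions() -> dict[tuple[str, int], str]:
    """(chrom, pos) → rsid fallback lookup shipped with the package.

    Coordinates are 1-based GRCh38 and exist only as a fallback for VCFs with
    empty ID columns; matching by rsID always takes precedence. Override with
    a custom YAML via :func:`read_vcf`'s ``positions`` argument.
    """
    text = (_resource_files("eightplex") / "data" / "panel_positions.yaml").read_text()
    return _parse_positions(yaml.safe_load(text))


def load_positions(path: str | Path) -> dict[tuple[str, int], str]:
    """Load a (chrom, pos) → rsid lookup from a YAML mapping file."""
    with open(path) as fh:
        return _parse_positions(yaml.safe_load(fh))


def _parse_positions(doc: Mapping) -> dict[tuple[str, int], str]:
    table: dict[tuple[str, int], str] = {}
    for rsid, loc in doc["positions"].items():
        if rsid not in _PANEL_BY_RSID:
            raise PanelValidationError(f"positions file: unknown rsID {rsid!r}")
        table[(str(loc["chrom"]).removeprefix("chr"), int(loc["pos"]))] = rsid
    return table


def read_vcf(
    path: str | Path,
    positions: Mapping[tuple[str, int], str] | None = None,
) -> list[SampleGenotypes]:
    """Read per-sample panel genotypes from a VCF (v4.2, GT field).

    Records are matched to the panel by the ID column first; records with no
    usable ID fall back to a (chrom, pos) lookup (GRCh38 by default). Sites
    absent from the VCF, half-calls, and ``./.`` become MISSING.
    """
    from cyvcf2 import VCF

    if positions is None:
        positions = default_positions()
    try:
        vcf = VCF(str(path))
    except Exception as exc:
        raise VcfParseError(f"{path}: cannot open VCF: {exc}") from exc

    sample_names = list(vcf.samples)
    if not sample_names:
        raise VcfParseError(f"{path}: VCF has no sample columns")
    samples = [SampleGenotypes(sample_id=name) for name in sample_names]

    for variant in vcf:
        rsid = None
        if variant.ID and variant.ID in _PANEL_BY_RSID:
            rsid = variant.ID
        elif not variant.ID or variant.ID == ".":
            rsid = positions.get(
                (str(variant.CHROM).removeprefix("chr"), variant.POS)
            )
        if rsid is None:
            continue
        snp = _PANEL_BY_RSID[rsid]
        if len(variant.ALT) > 1:
            raise VcfParseError(
                f"{path}: record {variant.CHROM}:{variant.POS} ({rsid}) "
                "is not biallelic"
            )
        alleles = [variant.REF] + list(variant.ALT)
        for i, gt in enumerate(variant.genotypes):
            a_idx, b_idx = gt[0], gt[1]
            if a_idx < 0 or b_idx < 0:  # ./., half-calls
                samples[i].calls[rsid] = GenotypeCall.missing(rsid)
                continue
            try:
                raw = (alleles[a_idx], alleles[b_idx])
            except IndexError:
                raise VcfParseError(
                    f"{path}: record {variant.CHROM}:{variant.POS} ({rsid}): "
                    f"GT index out of range for sample {sample_names[i]!r}"
                ) from None
            try:
                samples[i].calls[rsid] = normalize_genotype(raw, snp)
            except PanelValidationError as exc:
                raise PanelValidationError(
                    f"{path}: sample {sample_names[i]!r}: {exc}"
                ) from exc
    return [_complete_sample(s) for s in samples]
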