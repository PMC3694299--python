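"""Synthetic population-stratified cohorts with known error structure.

Genotypes are drawn per SNP under Hardy-Weinberg proportions from
population-specific allele frequencies (no linkage between panel SNPs).
Truth phenotypes are derived from the predictors themselves and then
perturbed: with probability ``discordance_rate`` a sample's bin is replaced
by one *incompatible* with its prediction, which makes the expected
evaluation error rate among called samples exactly the discordance rate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import yaml

try:
    from importlib.resources import files as _resource_files
except ImportError:  # pragma: no cover
    from importlib_resources import files as _resource_files

from .evaluate import COMPATIBILITY, NON_CALLS
from .eye import predict_eye
from .panel import (
    EYE_BINS,
    SKIN_BINS,
    GenotypeCall,
    PhenotypeRecord,
    SampleGenotypes,
    default_positions,
    get_snp,
    panel_rsids,
    write_genotype_table,
    write_phenotype_table,
)
from .skin import predict_skin

__all__ = ["CohortConfig", "ConfigError", "sample_genotypes", "assign_phenotypes", "generate"]


class ConfigError(ValueError):
    pass


@dataclass
class CohortConfig:
    """Simulator configuration.

    ``allele_freqs[pop][rsid]`` is the frequency of the first (alphabetical)
    allele of the panel pair for that SNP.
    """

    n_samples: int
    population_mix: dict[str, float]
    allele_freqs: dict[str, dict[str, float]]
    discordance_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise ConfigError("n_samples must be positive")
        if not 0.0 <= self.discordance_rate <= 1.0:
            raise ConfigError("discordance_rate must be in [0, 1]")
        total = sum(self.population_mix.values())
        if total <= 0:
            raise ConfigError("population weights must sum to a positive value")
        self.population_mix = {p: w / total for p, w in self.population_mix.items()}
        for pop in self.population_mix:
            freqs = self.allele_freqs.get(pop)
            if freqs is None:
                raise ConfigError(f"no allele frequencies for population {pop!r}")
            for rsid in panel_rsids():
                f = freqs.get(rsid)
                if f is None or not 0.0 <= f <= 1.0:
                    raise ConfigError(
                        f"population {pop!r}: invalid frequency for {rsid}: {f!r}"
                    )

    @classmethod
    def default(cls, n_samples: int = 1000, discordance_rate: float | None = None,
                seed: int = 0) -> "CohortConfig":
        """Config built from the packaged synthetic default frequencies."""
        doc = yaml.safe_load(
            (_resource_files("eightplex") / "data" / "default_frequencies.yaml").read_text()
        )
        return cls(
            n_samples=n_samples,
            population_mix=doc["population_mix"],
            allele_freqs=doc["allele_freqs"],
            discordance_rate=(
                doc.get("discordance_rate", 0.0)
                if discordance_rate is None
                else discordance_rate
            ),
            seed=seed,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        try:
            return cls(
                n_samples=int(doc["n_samples"]),
                population_mix=doc["population_mix"],
                allele_freqs=doc["allele_freqs"],
                discordance_rate=float(doc.get("discordance_rate", 0.0)),
                seed=int(doc.get("seed", 0)),
            )
        except KeyError as exc:
            raise ConfigError(f"{path}: missing config key {exc}") from exc

    def to_dict(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "population_mix": self.population_mix,
            "allele_freqs": self.allele_freqs,
            "discordance_rate": self.discordance_rate,
            "seed": self.seed,
        }


def sample_genotypes(cfg: CohortConfig) -> list[tuple[SampleGenotypes, str]]:
    """Draw a cohort of (sample, population) pairs, deterministic in the seed."""
    rng = np.random.default_rng(cfg.seed)
    pops = sorted(cfg.population_mix)
    weights = np.array([cfg.population_mix[p] for p in pops])
    assigned = rng.choice(len(pops), size=cfg.n_samples, p=weights)
    width = len(str(cfg.n_samples))
    cohort: list[tuple[SampleGenotypes, str]] = []
    for i, pop_idx in enumerate(assigned):
        pop = pops[pop_idx]
        s = SampleGenotypes(sample_id=f"sim{i + 1:0{width}d}")
        for rsid in panel_rsids():
            a0, a1 = get_snp(rsid).alleles
            p = cfg.allele_freqs[pop][rsid]
            u = rng.random()
            if u < p * p:
                gt = (a0, a0)
            elif u < p * p + 2 * p * (1 - p):
                gt = (a0, a1)
            else:
                gt = (a1, a1)
            s.calls[rsid] = GenotypeCall(rsid, gt)
        cohort.append((s, pop))
    return cohort


def _compatible_bins(label: str, trait: str) -> tuple[str, ...]:
    bins = EYE_BINS if trait == "eye" else SKIN_BINS
    if label in NON_CALLS:
        return tuple(bins)
    return tuple(b for b in bins if b in COMPATIBILITY[label])


def assign_phenotypes(
    cohort: Iterable[tuple[SampleGenotypes, str]],
    discordance_rate: float,
    seed: int,
) -> list[PhenotypeRecord]:
    """Derive truth bins from the predictors, with controlled discordance.

    Positive predictions pin the bin; negative ones draw uniformly from
    their compatible bins; non-calls draw uniformly from all three. With
    probability ``discordance_rate`` the bin is then replaced by a uniform
    draw from the bins incompatible with the prediction (no-op for
    non-calls, which have no incompatible bin).
    """
    rng = np.random.default_rng(seed)
    bins_all = {"eye": EYE_BINS, "skin": SKIN_BINS}
    records = []
    for s, pop in cohort:
        chosen: dict[str, str] = {}
        for trait, label in (
            ("eye", predict_eye(s).label),
            ("skin", predict_skin(s).label),
        ):
            compat = _compatible_bins(label, trait)
            bin_ = compat[rng.integers(len(compat))]
            incompat = tuple(b for b in bins_all[trait] if b not in compat)
            if incompat and rng.random() < discordance_rate:
                bin_ = incompat[rng.integers(len(incompat))]
            chosen[trait] = bin_
        records.append(
            PhenotypeRecord(
                sample_id=s.sample_id,
                population=pop,
                eye_bin=chosen["eye"],
                skin_bin=chosen["skin"],
            )
        )
    return records


def _write_vcf(cohort: list[tuple[SampleGenotypes, str]], path: Path) -> None:
    """Emit the cohort as a minimal VCF v4.2 (readable by the VCF reader)."""
    pos_by_rsid = {rsid: loc for loc, rsid in default_positions().items()}
    sample_ids = [s.sample_id for s, _ in cohort]
    records = sorted(
        panel_rsids(), key=lambda r: (int(pos_by_rsid[r][0]), pos_by_rsid[r][1])
    )
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in sorted({pos_by_rsid[r][0] for r in records}, key=int):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids) + "\n"
        )
        for rsid in records:
            chrom, pos = pos_by_rsid[rsid]
            ref, alt = get_snp(rsid).alleles
            idx = {ref: "0", alt: "1"}
            gts = []
            for s, _ in cohort:
                gt = s.genotype(rsid)
                gts.append("./." if gt is None else f"{idx[gt[0]]}/{idx[gt[1]]}")
            fh.write(
                f"{chrom}\t{pos}\t{rsid}\t{ref}\t{alt}\t.\t.\t.\tGT\t"
                + "\t".join(gts) + "\n"
            )


def generate(
    cfg: CohortConfig, outdir: str | Path, write_vcf: bool = False
) -> dict[str, Path]:
    """Write a cohort (genotype TSV + phenotype TSV + manifest, optionally a
    VCF) and return the paths. Byte-identical for identical config+seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = sample_genotypes(cfg)
    truths = assign_phenotypes(cohort, cfg.discordance_rate, cfg.seed + 1)

    paths = {
        "genotypes": outdir / "genotypes.tsv",
        "phenotypes": outdir / "phenotypes.tsv",
        "manifest": outdir / "manifest.json",
    }
    write_genotype_table([s for s, _ in cohort], paths["genotypes"])
    write_phenotype_table(truths, paths["phenotypes"])
    manifest = {"config": cfg.to_dict(), "files": {k: p.name for k, p in paths.items()}}
    if write_vcf:
        paths["vcf"] = outdir / "cohort.vcf"
        manifest["files"]["vcf"] = "cohort.vcf"
        _write_vcf(cohort, paths["vcf"])
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return paths
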