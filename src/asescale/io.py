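"""File formats, run configuration and the end-to-end pipeline.

Genotypes travel as VCF (diploid GT, the ALT allele is the counted allele)
or as a dosage TSV (rows = individuals, columns = variant ids, values
0/1/2).  Phenotypes are TSV with columns ``id``, ``phenotype`` and
``weight``.  Every TSV the pipeline writes starts with a comment line
recording the configuration hash and seed, so outputs are traceable to the
run that produced them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .blup import SNPBLUP, PhenotypeSet
from .coding import GenotypeMatrix, apply_variant_filters
from .compare import overall_comparison, theory_overlay
from .scan import GammaScan
from .simulate import SimulationConfig, simulate_dataset
from .theory import FrequencyModel, Scenario

__all__ = [
    "RunConfig",
    "read_genotypes",
    "write_genotypes_vcf",
    "write_genotypes_tsv",
    "read_phenotypes",
    "write_phenotypes",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


def _read_vcf(path: str | Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    columns: list[np.ndarray] = []
    variant_ids: list[str] = []
    for variant in vcf:
        if len(variant.ALT) != 1:
            raise ValueError(
                f"variant {variant.ID or variant.POS} is not biallelic"
            )
        counts = np.empty(len(samples), dtype=np.int8)
        for i, gt in enumerate(variant.genotypes):
            alleles = gt[:-1]
            if len(alleles) != 2:
                raise ValueError(
                    f"variant {variant.ID or variant.POS}, sample {samples[i]}: "
                    f"ploidy {len(alleles)} is not supported"
                )
            if any(a < 0 for a in alleles):
                raise ValueError(
                    f"missing genotype at variant {variant.ID or variant.POS}, "
                    f"sample {samples[i]}"
                )
            counts[i] = sum(1 for a in alleles if a == 1)
        columns.append(counts)
        variant_ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
    if not columns:
        raise ValueError(f"no variants in {path}")
    return GenotypeMatrix(
        np.column_stack(columns), sample_ids=samples, variant_ids=variant_ids
    )


def _read_dosage_tsv(path: str | Path) -> GenotypeMatrix:
    table = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    values = table.to_numpy()
    if not np.isin(values, (0, 1, 2)).all():
        bad = np.argwhere(~np.isin(values, (0, 1, 2)))[0]
        raise ValueError(
            f"dosage value {values[tuple(bad)]!r} at row {table.index[bad[0]]!r}, "
            f"column {table.columns[bad[1]]!r} is not in {{0, 1, 2}}"
        )
    return GenotypeMatrix(
        values.astype(np.int8),
        sample_ids=[str(s) for s in table.index],
        variant_ids=[str(v) for v in table.columns],
    )


def read_genotypes(path: str | Path, format: str | None = None) -> GenotypeMatrix:
    """Read a genotype matrix from VCF or dosage TSV.

    The format is inferred from the suffix when not given.  Missing
    genotypes and non-diploid records are rejected with the offending
    record named.
    """
    path = Path(path)
    if format is None:
        format = "vcf" if ".vcf" in path.suffixes else "dosage_tsv"
    if format == "vcf":
        return _read_vcf(path)
    if format == "dosage_tsv":
        return _read_dosage_tsv(path)
    raise ValueError(f"unknown genotype format: {format!r}")


def write_genotypes_vcf(X: GenotypeMatrix, path: str | Path) -> None:
    """Write as minimal VCF: one biallelic record per locus, ALT counted."""
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=asescale\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(X.sample_ids)
            + "\n"
        )
        for j, vid in enumerate(X.variant_ids):
            gts = "\t".join(gt_strings[int(v)] for v in X.values[:, j])
            fh.write(f"1\t{j + 1}\t{vid}\tA\tC\t.\tPASS\t.\tGT\t{gts}\n")


def write_genotypes_tsv(
    X: GenotypeMatrix, path: str | Path, header: str | None = None
) -> None:
    """Write the dosage matrix (individuals x loci) as TSV."""
    table = pd.DataFrame(X.values, index=X.sample_ids, columns=X.variant_ids)
    table.index.name = "id"
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        table.to_csv(fh, sep="\t")


def read_phenotypes(
    path: str | Path, sample_ids: list[str] | None = None
) -> PhenotypeSet:
    """Read a phenotype TSV (id, phenotype, weight).

    A missing weight column defaults to 1 with a logged warning.  When
    ``sample_ids`` is given the phenotypes are aligned to that order;
    individuals without a phenotype are dropped with a logged count, and a
    completely empty overlap is rejected.
    """
    table = pd.read_csv(path, sep="\t", comment="#", dtype={"id": str})
    if "id" not in table.columns or "phenotype" not in table.columns:
        raise ValueError("phenotype file must have 'id' and 'phenotype' columns")
    if "weight" not in table.columns:
        logger.warning("no 'weight' column in %s; defaulting all weights to 1", path)
        table["weight"] = 1.0
    if (table["weight"] <= 0).any():
        raise ValueError("non-positive weight in phenotype file")
    if sample_ids is not None:
        table = table.set_index("id")
        present = [s for s in sample_ids if s in table.index]
        if not present:
            raise ValueError("no overlap between genotype and phenotype ids")
        dropped = len(sample_ids) - len(present)
        if dropped:
            logger.warning("%d genotyped individuals have no phenotype", dropped)
        table = table.loc[present].reset_index()
    return PhenotypeSet(
        y=table["phenotype"].to_numpy(float),
        weights=table["weight"].to_numpy(float),
        ids=list(table["id"]),
    )


def write_phenotypes(
    pheno: PhenotypeSet, path: str | Path, header: str | None = None
) -> None:
    table = pd.DataFrame(
        {"id": pheno.ids, "phenotype": pheno.y, "weight": pheno.weights}
    )
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        table.to_csv(fh, sep="\t", index=False)


@dataclass(frozen=True)
class RunConfig:
    """Flat configuration of the full demonstration pipeline."""

    n_individuals: int = 500
    n_snps: int = 2000
    h2: float = 0.5
    gamma_true: float = -1.0
    total_additive_variance: float = 1.0
    mean_weight: float = 549.0
    weight_model: str = "constant"
    freq_kind: str = "ushaped"
    ne: int = 65
    mutation_rate: float = 1e-8
    min_minor_copies: int = 5
    train_fraction: float = 0.6
    seed: int = 1
    out_dir: str = "asescale_run"

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for f in dataclasses.fields(self):
                fh.write(f"{f.name}={getattr(self, f.name)}\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        raw: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            raw[key.strip()] = value.strip()
        kwargs: dict[str, object] = {}
        for f in dataclasses.fields(cls):
            if f.name in raw:
                kwargs[f.name] = _convert(f.type, raw[f.name])
        return cls(**kwargs)

    @property
    def hash(self) -> str:
        blob = ";".join(
            f"{f.name}={getattr(self, f.name)}" for f in dataclasses.fields(self)
        )
        return hashlib.sha1(blob.encode()).hexdigest()[:8]

    def simulation_config(self) -> SimulationConfig:
        model = (
            FrequencyModel("uniform")
            if self.freq_kind == "uniform"
            else FrequencyModel("ushaped", ne=self.ne, mutation_rate=self.mutation_rate)
        )
        return SimulationConfig(
            n_individuals=self.n_individuals,
            n_snps=self.n_snps,
            h2=self.h2,
            gamma_true=self.gamma_true,
            total_additive_variance=self.total_additive_variance,
            mean_weight=self.mean_weight,
            weight_model=self.weight_model,  # type: ignore[arg-type]
            seed=self.seed,
            frequency_model=model,
        )


def _convert(type_name: object, value: str):
    name = type_name if isinstance(type_name, str) else getattr(
        type_name, "__name__", str(type_name)
    )
    if name == "int":
        return int(value)
    if name == "float":
        return float(value)
    return value


def _write_table(table: pd.DataFrame, path: Path, header: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {header}\n")
        table.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> Path:
    """simulate -> filter -> fit (gamma 0 and -1) -> compare -> scan.

    Every stage writes its TSV artifacts into ``config.out_dir``; a stage
    failure raises with the stage named, keeping earlier outputs on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tag = f"asescale config={config.hash} seed={config.seed}"
    config.to_file(out / "config.txt")

    stage = "simulate"
    try:
        data = simulate_dataset(config.simulation_config())
        write_genotypes_vcf(data.genotypes, out / "genotypes.vcf")
        write_genotypes_tsv(data.genotypes, out / "genotypes.tsv", header=tag)
        write_phenotypes(data.phenotypes, out / "phenotypes.tsv", header=tag)
        _write_table(
            pd.DataFrame(
                {
                    "variant_id": data.genotypes.variant_ids,
                    "true_frequency": data.true_frequencies,
                    "true_effect": data.true_effects.effects,
                }
            ),
            out / "true_effects.tsv",
            tag,
        )

        stage = "filter"
        filtered, report = apply_variant_filters(
            data.genotypes, min_minor_copies=config.min_minor_copies
        )
        _write_table(report, out / "removed_variants.tsv", tag)
        write_genotypes_tsv(filtered, out / "genotypes_filtered.tsv", header=tag)

        stage = "fit"
        fits = {}
        for gamma in (0.0, -1.0):
            est = SNPBLUP(gamma=gamma).fit(
                filtered, data.phenotypes.y, sample_weight=data.phenotypes.weights
            )
            fits[gamma] = est
            label = "rrc" if gamma == 0.0 else "rrcs"
            _write_table(
                pd.DataFrame(
                    {
                        "variant_id": filtered.variant_ids,
                        "maf": np.minimum(est.p_, 1 - est.p_),
                        "b_hat": est.coef_,
                        "ase": est.ase_,
                    }
                ),
                out / f"fit_{label}_snps.tsv",
                tag,
            )
            _write_table(
                pd.DataFrame(
                    {
                        "id": filtered.sample_ids,
                        "dgv": est.dgv_,
                        "predicted": est.dgv_ + est.intercept_,
                    }
                ),
                out / f"fit_{label}_individuals.tsv",
                tag,
            )
            _write_table(
                pd.DataFrame(
                    [
                        {
                            "gamma": gamma,
                            "mu_hat": est.intercept_,
                            "sigma_a2": est.varcomp_.sigma_a2,
                            "sigma_e2": est.varcomp_.sigma_e2,
                            "h2": est.varcomp_.h2,
                            "logL_reml": est.loglik_,
                        }
                    ]
                ),
                out / f"fit_{label}_summary.tsv",
                tag,
            )

        stage = "compare"
        report_cmp = overall_comparison(
            fits[0.0].result_, fits[-1.0].result_, bin_width=0.05
        )
        scenario = Scenario(
            h2=fits[0.0].varcomp_.h2,
            n_individuals=filtered.n_individuals,
            n_snps=filtered.n_snps,
            frequency_model=config.simulation_config().frequency_model,
        )
        _write_table(
            theory_overlay(report_cmp.per_maf, scenario),
            out / "comparison_per_maf.tsv",
            tag,
        )
        _write_table(
            pd.DataFrame(
                [
                    {
                        "dgv_correlation": report_cmp.dgv_correlation,
                        "dgv_slope": report_cmp.dgv_slope,
                        "dgv_variance_rrc": report_cmp.dgv_variance_a,
                        "dgv_variance_rrcs": report_cmp.dgv_variance_b,
                        "ase_correlation": report_cmp.ase_correlation,
                    }
                ]
            ),
            out / "comparison_overall.tsv",
            tag,
        )

        stage = "scan"
        scan = GammaScan(
            criterion="both", train_fraction=config.train_fraction
        ).fit(filtered, data.phenotypes.y, sample_weight=data.phenotypes.weights)
        _write_table(scan.result_.to_frame(), out / "gamma_scan.tsv", tag)
        (out / "gamma_scan_summary.txt").write_text(
            f"# {tag}\n"
            f"best_gamma_loglik={scan.best_gamma_loglik_}\n"
            f"best_gamma_msep={scan.best_gamma_msep_}\n"
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    return out
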