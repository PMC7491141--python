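"""Core data containers for the mediation-analysis pipeline.

Samples, methylation beta values, CpG annotation, genotype dosages, and the
run configuration are the only objects the analysis stages exchange; every
reader in :mod:`methmediate.io` validates into one of these types and no
downstream stage re-reads raw files.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CELL_TYPES = ["cd4t", "cd8t", "nk", "b", "mono", "gran"]
CELL_PROP_COLUMNS = [f"prop_{c}" for c in CELL_TYPES]

EXPOSURE_GROUPS = ("persistent", "none", "inconsistent")
RACES = ("caucasian", "african_american", "other")
SEXES = ("male", "female")

#: covariates of the mediator and outcome models: sex, age, race, smoking,
#: antiviral-adherence, white blood cell count, and the five cell-type
#: proportions other than CD4+ T cells.
MEDIATION_COVARIATES = [
    "sex", "age", "race", "smoking", "adherence", "wbc", "cell_props_ex_cd4",
]
#: EWA models add technical negative-control PCs on top of the above.
EWA_COVARIATES = MEDIATION_COVARIATES + ["neg_ctrl_pcs"]
#: SNP-association covariates for Mendelian-randomization steps.
MR_SNP_COVARIATES = ["age", "sex", "race", "ancestry_pcs"]
#: outcome-association covariates for MR step 2 (race optional via flag).
MR_STEP2_OUTCOME_COVARIATES = ["age", "sex", "ancestry_pcs"]

_REQUIRED_SAMPLE_COLUMNS = [
    "sample_id", "exposure_group", "exposure_freq", "sex", "age", "race",
    "smoking", "adherence", "alcohol_auditc", "cannabis_freq", "opioid_freq",
    "wbc", *CELL_PROP_COLUMNS, "vacs_at_draw", "vacs_avg_after",
    "surv_years", "event",
]


class ValidationError(ValueError):
    """Raised when an input file or container violates a data invariant."""


@dataclass
class SampleTable:
    """Per-sample phenotypes, covariates and outcomes.

    Wraps a :class:`pandas.DataFrame` with one row per sample.  Columns
    ``ncpc1..ncpcK`` hold negative-control principal components and
    ``apc1..apc5`` hold genetic-ancestry principal components when present.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        df = self.df
        missing = [c for c in _REQUIRED_SAMPLE_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"sample table missing required columns: {missing}")
        if df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        bad_group = set(df["exposure_group"]) - set(EXPOSURE_GROUPS)
        if bad_group:
            raise ValidationError(f"unknown exposure_group values: {sorted(bad_group)}")
        freq = df["exposure_freq"].to_numpy()
        if not np.isin(freq, np.arange(6)).all():
            raise ValidationError("exposure_freq must be integers in 0..5")
        props = df[CELL_PROP_COLUMNS].to_numpy(float)
        if (props < 0).any():
            raise ValidationError("negative cell proportions")
        sums = props.sum(axis=1)
        off = np.abs(sums - 1.0) > 1e-6
        if off.any():
            i = int(np.argmax(off))
            raise ValidationError(
                f"cell proportions of sample {df['sample_id'].iloc[i]!r} "
                f"sum to {sums[i]:.6f}, expected 1"
            )
        surv = df["surv_years"].to_numpy(float)
        if (surv[~np.isnan(surv)] <= 0).any():
            raise ValidationError("surv_years must be positive where present")

    # -- convenience -----------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def sample_ids(self) -> list[str]:
        return self.df["sample_id"].tolist()

    def ancestry_pc_columns(self) -> list[str]:
        return sorted(
            (c for c in self.df.columns if c.startswith("apc")),
            key=lambda c: int(c[3:]),
        )

    def neg_ctrl_pc_columns(self) -> list[str]:
        return sorted(
            (c for c in self.df.columns if c.startswith("ncpc")),
            key=lambda c: int(c[4:]),
        )

    def exposure_indicator(self) -> pd.Series:
        """1 for persistent use, 0 for no use, NaN for inconsistent reporters.

        Two-group analyses (EWA exposure scan, mediation) drop the NaN rows,
        mirroring the consistent-reporters design.
        """
        mapping = {"persistent": 1.0, "none": 0.0, "inconsistent": np.nan}
        return self.df["exposure_group"].map(mapping)

    def two_group_subset(self) -> "SampleTable":
        keep = self.df["exposure_group"].isin(["persistent", "none"])
        return SampleTable(self.df.loc[keep].reset_index(drop=True))


def design_matrix(
    samples: SampleTable, terms: list[str]
) -> tuple[np.ndarray, list[str]]:
    """Build a regression design matrix (intercept first) from term names.

    Term names are sample-table columns, or one of the expanding shorthands
    ``sex`` (female indicator), ``race`` (two dummies, caucasian reference),
    ``cell_props_ex_cd4``, ``cell_props``, ``neg_ctrl_pcs``, ``ancestry_pcs``.
    """
    df = samples.df
    cols: list[np.ndarray] = [np.ones(len(df))]
    names: list[str] = ["intercept"]

    def add(name: str, values: np.ndarray) -> None:
        cols.append(np.asarray(values, float))
        names.append(name)

    for term in terms:
        if term == "sex":
            add("sex_female", (df["sex"] == "female").to_numpy(float))
        elif term == "race":
            add("race_african_american",
                (df["race"] == "african_american").to_numpy(float))
            add("race_other", (df["race"] == "other").to_numpy(float))
        elif term == "cell_props_ex_cd4":
            for c in CELL_TYPES:
                if c != "cd4t":
                    add(f"prop_{c}", df[f"prop_{c}"].to_numpy(float))
        elif term == "cell_props":
            # drop one (granulocytes) to avoid the sum-to-one collinearity
            for c in CELL_TYPES[:-1]:
                add(f"prop_{c}", df[f"prop_{c}"].to_numpy(float))
        elif term == "neg_ctrl_pcs":
            for c in samples.neg_ctrl_pc_columns():
                add(c, df[c].to_numpy(float))
        elif term == "ancestry_pcs":
            for c in samples.ancestry_pc_columns():
                add(c, df[c].to_numpy(float))
        elif term in df.columns:
            add(term, df[term].to_numpy(float))
        else:
            raise KeyError(f"unknown design term {term!r}")
    return np.column_stack(cols), names


@dataclass
class CpgAnnotation:
    """CpG genomic annotation: 1-based positions, nearest gene, island context."""

    df: pd.DataFrame

    REQUIRED = ["cpg", "chr", "pos", "gene"]

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValidationError(f"annotation missing columns: {missing}")
        if self.df["cpg"].duplicated().any():
            raise ValidationError("duplicate cpg ids in annotation")
        if (self.df["pos"].to_numpy(int) < 1).any():
            raise ValidationError("annotation positions must be >= 1 (1-based)")
        for optional in ("gene_group", "island_relation"):
            if optional not in self.df.columns:
                self.df[optional] = ""

    @property
    def cpg_ids(self) -> list[str]:
        return self.df["cpg"].tolist()

    def locus(self, cpg: str) -> tuple[str, int]:
        row = self.df.loc[self.df["cpg"] == cpg]
        if row.empty:
            raise KeyError(f"cpg {cpg!r} not in annotation")
        return str(row["chr"].iloc[0]), int(row["pos"].iloc[0])


@dataclass
class BetaMatrix:
    """Methylation beta values, CpGs x samples, each in [0, 1]."""

    cpg_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    validate_range: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.shape != (len(self.cpg_ids), len(self.sample_ids)):
            raise ValidationError(
                f"beta matrix shape {self.values.shape} does not match "
                f"{len(self.cpg_ids)} CpGs x {len(self.sample_ids)} samples"
            )
        if len(set(self.cpg_ids)) != len(self.cpg_ids):
            raise ValidationError("duplicate cpg ids in beta matrix")
        if self.validate_range:
            bad = (self.values < 0) | (self.values > 1)
            if bad.any():
                i, j = map(int, np.argwhere(bad)[0])
                raise ValidationError(
                    f"beta value {self.values[i, j]} outside [0, 1] at "
                    f"cpg {self.cpg_ids[i]!r}, sample {self.sample_ids[j]!r}"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row(self, cpg: str) -> np.ndarray:
        try:
            i = self.cpg_ids.index(cpg)
        except ValueError:
            raise KeyError(f"cpg {cpg!r} not in beta matrix") from None
        return self.values[i]

    def subset_cpgs(self, cpgs: list[str]) -> "BetaMatrix":
        index = {c: i for i, c in enumerate(self.cpg_ids)}
        rows = [index[c] for c in cpgs]
        return BetaMatrix(list(cpgs), list(self.sample_ids),
                          self.values[rows], validate_range=self.validate_range)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cpg_ids,
                            columns=self.sample_ids)


@dataclass
class GenotypeMatrix:
    """SNP dosages (rows = SNPs, columns = samples), values in [0, 2]."""

    snp_ids: list[str]
    chr: list[str]
    pos: list[int]
    sample_ids: list[str]
    dosages: np.ndarray
    ref: list[str] = field(default_factory=list)
    alt: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, float)
        p = len(self.snp_ids)
        if self.dosages.shape != (p, len(self.sample_ids)):
            raise ValidationError("dosage matrix shape mismatch")
        if len(self.chr) != p or len(self.pos) != p:
            raise ValidationError("chr/pos length mismatch")
        if ((self.dosages < 0) | (self.dosages > 2)).any():
            raise ValidationError("dosages outside [0, 2]")
        if not self.ref:
            self.ref = ["A"] * p
        if not self.alt:
            self.alt = ["G"] * p

    @property
    def maf(self) -> np.ndarray:
        """Minor allele frequency per SNP (folded allele frequency)."""
        af = self.dosages.mean(axis=1) / 2.0
        return np.minimum(af, 1.0 - af)

    def row(self, snp: str) -> np.ndarray:
        try:
            i = self.snp_ids.index(snp)
        except ValueError:
            raise KeyError(f"snp {snp!r} not in genotypes") from None
        return self.dosages[i]

    def subset_snps(self, snps: list[str]) -> "GenotypeMatrix":
        index = {s: i for i, s in enumerate(self.snp_ids)}
        rows = [index[s] for s in snps]
        return GenotypeMatrix(
            list(snps),
            [self.chr[i] for i in rows],
            [self.pos[i] for i in rows],
            list(self.sample_ids),
            self.dosages[rows],
            [self.ref[i] for i in rows],
            [self.alt[i] for i in rows],
        )

    def filter_maf(self, min_maf: float) -> "GenotypeMatrix":
        keep = [s for s, m in zip(self.snp_ids, self.maf) if m >= min_maf]
        return self.subset_snps(keep)


@dataclass
class RunConfig:
    """Analysis thresholds and bookkeeping, recorded in every output header.

    Defaults follow the pipeline's published operating points: EWA candidate
    cutoff p < 0.001, cis-meQTL cutoff p < 0.01 within a closed 1 Mb window,
    LD pruning at r^2 < 0.1, external instruments at p < 1e-5, and a MAF
    floor of 0.01 for genotypes.
    """

    ewa_p: float = 1e-3
    meqtl_p: float = 1e-2
    ld_r2: float = 0.1
    cis_window: int = 1_000_000
    instrument_p: float = 1e-5
    min_maf: float = 0.01
    bootstrap_reps: int = 10_000
    rng_seed: int = 0
    output_dir: str = "."

    def __post_init__(self) -> None:
        for name in ("ewa_p", "meqtl_p", "instrument_p"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValidationError(f"{name}={v} outside (0, 1]")
        if not 0 < self.ld_r2 <= 1:
            raise ValidationError("ld_r2 outside (0, 1]")
        if self.cis_window < 0:
            raise ValidationError("cis_window must be non-negative")
        if self.bootstrap_reps < 1:
            raise ValidationError("bootstrap_reps must be >= 1")

    def header_lines(self) -> list[str]:
        items = dataclasses.asdict(self)
        return [f"# methmediate {k}={v}" for k, v in items.items()]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})
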