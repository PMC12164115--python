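"""Input/output and shared domain types.

Somatic mutation tables arrive as MAF-like TSV files (one row per SNV per
sample) already joined with per-mutation RNA allele counts; tumor purity and
allele-specific copy number may be merged in or supplied as a separate
segment table.  Column names are remappable through a dialect mapping so
MC3-style MAF headers (``Tumor_Sample_Barcode``, ``Variant_Classification``,
...) load without renaming upstream.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml


class VarClass(str, enum.Enum):
    """Functional classification of a single-nucleotide variant."""

    SYNONYMOUS = "synonymous"
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    SPLICE_SITE = "splice_site"
    NONSTOP = "nonstop"
    OTHER = "other"


#: classes counted as nonsynonymous (protein-affecting) throughout
NONSYNONYMOUS = frozenset(
    {VarClass.MISSENSE, VarClass.NONSENSE, VarClass.SPLICE_SITE, VarClass.NONSTOP}
)

#: MAF Variant_Classification strings -> VarClass (MC3 dialect)
DEFAULT_CLASS_MAP: dict[str, VarClass] = {
    "Silent": VarClass.SYNONYMOUS,
    "Missense_Mutation": VarClass.MISSENSE,
    "Nonsense_Mutation": VarClass.NONSENSE,
    "Splice_Site": VarClass.SPLICE_SITE,
    "Nonstop_Mutation": VarClass.NONSTOP,
    # canonical internal names map to themselves
    "synonymous": VarClass.SYNONYMOUS,
    "missense": VarClass.MISSENSE,
    "nonsense": VarClass.NONSENSE,
    "splice_site": VarClass.SPLICE_SITE,
    "nonstop": VarClass.NONSTOP,
    "other": VarClass.OTHER,
}

#: canonical column names of a cohort mutation table
MUTATION_COLUMNS = [
    "sample_id",
    "gene",
    "chrom",
    "pos",
    "ref_allele",
    "alt_allele",
    "var_class",
    "dna_vaf",
    "dna_alt",
    "dna_depth",
    "rna_alt",
    "rna_ref",
    "nmd_score",
    "purity",
    "ncn",
    "tcn",
]

REQUIRED_COLUMNS = [
    "sample_id",
    "gene",
    "chrom",
    "pos",
    "ref_allele",
    "alt_allele",
    "var_class",
    "rna_alt",
    "rna_ref",
]

#: MAF-style header -> canonical name (used on top of any user dialect map)
DEFAULT_DIALECT: dict[str, str] = {
    "Tumor_Sample_Barcode": "sample_id",
    "Hugo_Symbol": "gene",
    "Chromosome": "chrom",
    "Start_Position": "pos",
    "Reference_Allele": "ref_allele",
    "Tumor_Seq_Allele2": "alt_allele",
    "Variant_Classification": "var_class",
}


class SchemaError(ValueError):
    """A required column is absent from an input table."""


class ValidationError(ValueError):
    """Rows violate the mutation-record invariants."""


@dataclass(frozen=True)
class MutationRecord:
    """One somatic SNV in one sample with DNA and RNA allele counts."""

    sample_id: str
    gene: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    var_class: VarClass
    dna_vaf: float = np.nan
    dna_alt: int = 0
    dna_depth: int = 0
    rna_alt: int = 0
    rna_ref: int = 0
    nmd_score: float = np.nan
    purity: float = np.nan
    ncn: int = 2
    tcn: int = 2

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos}")
        if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
            raise ValidationError("alleles must be single nucleotides")
        if self.ref_allele == self.alt_allele:
            raise ValidationError("ref_allele equals alt_allele")
        if self.dna_alt > self.dna_depth:
            raise ValidationError(
                f"dna_alt ({self.dna_alt}) exceeds dna_depth ({self.dna_depth})"
            )
        if self.rna_alt < 0 or self.rna_ref < 0:
            raise ValidationError("RNA allele counts must be non-negative")
        if not np.isnan(self.dna_vaf) and not 0.0 <= self.dna_vaf <= 1.0:
            raise ValidationError(f"dna_vaf out of [0,1]: {self.dna_vaf}")
        if not np.isnan(self.purity) and not 0.0 < self.purity <= 1.0:
            raise ValidationError(f"purity out of (0,1]: {self.purity}")
        if self.tcn < 1 or self.ncn < 1:
            raise ValidationError("copy numbers must be >= 1")


@dataclass
class CohortTable:
    """All mutation records of one cancer-type cohort.

    ``df`` uses the canonical :data:`MUTATION_COLUMNS`; preprocessing stages
    append derived columns (``rna_depth``, ``rna_vaf``, ``weight``, ...) in
    place of wrapping each row in a new object.
    """

    cancer_type: str
    df: pd.DataFrame

    @property
    def n_cohort(self) -> int:
        """Number of distinct samples (the cohort size of the rate formula)."""
        return int(self.df["sample_id"].nunique())

    def __len__(self) -> int:
        return len(self.df)

    def copy(self) -> "CohortTable":
        return CohortTable(self.cancer_type, self.df.copy())


@dataclass
class GeneAnnotation:
    """Cancer-gene membership and oncogene/TSG roles.

    A cancer-specific role takes precedence over the pan-cancer role for the
    active cancer type.
    """

    cgc_genes: set[str] = field(default_factory=set)
    oncogenes: set[str] = field(default_factory=set)
    tsgs: set[str] = field(default_factory=set)
    chromosome_of_gene: dict[str, str] = field(default_factory=dict)


@dataclass
class GeneTestResult:
    """Per gene x mutation-class-subset test outcome."""

    gene: str
    class_subset: str  # missense_only | nonsense_only | splice_only | all_nonsyn
    n_case: int
    effect_size: float
    p_boot: list[float]
    p_geomean: float
    q_value: float = np.nan
    driver_flag: bool = False


def _validate_mutation_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Vectorised invariant checks; returns the frame of valid rows.

    Raises :class:`ValidationError` listing offending rows when any row
    fails, so bad inputs never load silently.
    """
    problems: list[str] = []
    checks = [
        (df["pos"] < 1, "pos < 1"),
        (df["ref_allele"].astype(str).str.len() != 1, "ref_allele not a single base"),
        (df["alt_allele"].astype(str).str.len() != 1, "alt_allele not a single base"),
        (df["ref_allele"] == df["alt_allele"], "ref_allele == alt_allele"),
        (df["rna_alt"] < 0, "rna_alt < 0"),
        (df["rna_ref"] < 0, "rna_ref < 0"),
    ]
    if "dna_alt" in df and "dna_depth" in df:
        checks.append((df["dna_alt"] > df["dna_depth"], "dna_alt > dna_depth"))
    if "dna_vaf" in df:
        checks.append(
            ((df["dna_vaf"] < 0) | (df["dna_vaf"] > 1), "dna_vaf outside [0,1]")
        )
    if "purity" in df:
        checks.append(
            ((df["purity"] <= 0) | (df["purity"] > 1), "purity outside (0,1]")
        )
    for mask, msg in checks:
        mask = mask.fillna(False)
        if mask.any():
            rows = df.index[mask].tolist()[:10]
            problems.append(f"{msg} at rows {rows}")
    if problems:
        raise ValidationError("; ".join(problems))

    dup = df.duplicated(subset=["sample_id", "chrom", "pos", "alt_allele"])
    if dup.any():
        raise ValidationError(
            f"duplicate (sample, chrom, pos, alt) at rows {df.index[dup].tolist()[:10]}"
        )
    return df


def read_mutation_table(
    path: str | Path,
    dialect: Mapping[str, str] | str | Path | None = None,
    cancer_type: str = "cohort",
    class_map: Mapping[str, VarClass] | None = None,
) -> CohortTable:
    """Load and validate a MAF-like mutation/RNA-count TSV.

    Parameters
    ----------
    path
        Tab-separated file with one row per SNV per sample.
    dialect
        Optional mapping from file column names to canonical names, or a
        path to a YAML file holding one.  MC3 MAF headers are always
        recognised.
    cancer_type
        Label stored on the returned :class:`CohortTable`.
    class_map
        Mapping from classification strings to :class:`VarClass`; unmapped
        strings become ``other``.
    """
    if isinstance(dialect, (str, Path)):
        with open(dialect) as fh:
            dialect = yaml.safe_load(fh) or {}
    rename = dict(DEFAULT_DIALECT)
    if dialect:
        rename.update({str(k): str(v) for k, v in dialect.items()})

    df = pd.read_csv(path, sep="\t", na_values=[".", ""], dtype={"chrom": str})
    df = df.rename(columns=rename)

    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    cmap = dict(DEFAULT_CLASS_MAP)
    if class_map:
        cmap.update(class_map)
    df["var_class"] = (
        df["var_class"].map(lambda s: cmap.get(str(s), VarClass.OTHER)).map(lambda v: v.value)
    )

    for col, default in (("nmd_score", np.nan), ("purity", np.nan), ("dna_vaf", np.nan),
                         ("dna_alt", 0), ("dna_depth", 0), ("ncn", 2), ("tcn", 2)):
        if col not in df.columns:
            df[col] = default
    df["pos"] = df["pos"].astype(int)
    for col in ("dna_alt", "dna_depth", "rna_alt", "rna_ref", "ncn", "tcn"):
        df[col] = df[col].fillna(0).astype(int)
    df.loc[df["ncn"] < 1, "ncn"] = 2
    df.loc[df["tcn"] < 1, "tcn"] = 1

    df = _validate_mutation_frame(df[MUTATION_COLUMNS].copy())
    return CohortTable(cancer_type=cancer_type, df=df.reset_index(drop=True))


def join_copy_number(
    cohort: CohortTable, segments: pd.DataFrame | str | Path
) -> CohortTable:
    """Attach purity/allele-specific copy number from a segment table.

    ``segments`` needs columns ``sample_id, chrom, start, end, purity, tcn``
    (optionally ``ncn``); intervals are half-open ``[start, end)``.
    Mutations falling in no segment keep their existing values.
    """
    if isinstance(segments, (str, Path)):
        segments = pd.read_csv(segments, sep="\t", dtype={"chrom": str})
    df = cohort.df.copy()
    seg = segments.sort_values(["sample_id", "chrom", "start"])
    for (sid, chrom), grp in seg.groupby(["sample_id", "chrom"], sort=False):
        sel = (df["sample_id"] == sid) & (df["chrom"] == chrom)
        if not sel.any():
            continue
        pos = df.loc[sel, "pos"].to_numpy()
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        inside = (idx >= 0) & (pos < ends[np.clip(idx, 0, len(ends) - 1)])
        rows = df.index[sel][inside]
        hit = grp.iloc[idx[inside]]
        df.loc[rows, "purity"] = hit["purity"].to_numpy()
        df.loc[rows, "tcn"] = hit["tcn"].to_numpy().astype(int)
        if "ncn" in grp.columns:
            df.loc[rows, "ncn"] = hit["ncn"].to_numpy().astype(int)
    return CohortTable(cohort.cancer_type, df)


def read_gene_lists(
    cgc_path: str | Path,
    roles_path: str | Path | None = None,
    cancer_type: str | None = None,
    chromosomes_path: str | Path | None = None,
) -> GeneAnnotation:
    """Load cancer-gene membership and oncogene/TSG roles.

    ``cgc_path`` is one symbol per line.  ``roles_path`` is a two- or
    three-column TSV ``gene<TAB>role[<TAB>cancer_type]`` with role tokens
    ``oncogene``/``tsg``; a row carrying the active ``cancer_type`` overrides
    a pan-cancer row (empty third column) for that gene.
    """
    cgc_path = Path(cgc_path)
    text = cgc_path.read_text().strip()
    if not text:
        raise ValueError(f"empty gene list: {cgc_path}")
    cgc = {line.split("\t")[0].strip() for line in text.splitlines() if line.strip()}

    ann = GeneAnnotation(cgc_genes=cgc)
    if roles_path is not None:
        pan: dict[str, str] = {}
        specific: dict[str, str] = {}
        for line in Path(roles_path).read_text().splitlines():
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            gene = parts[0].strip()
            role = parts[1].strip().lower() if len(parts) > 1 else ""
            ctx = parts[2].strip() if len(parts) > 2 else ""
            if not role:
                continue
            if role not in ("oncogene", "tsg"):
                raise ValueError(f"unknown role token {role!r} for gene {gene}")
            if ctx and cancer_type and ctx == cancer_type:
                specific[gene] = role
            elif not ctx:
                pan[gene] = role
        merged = {**pan, **specific}  # cancer-specific overrides pan-cancer
        ann.oncogenes = {g for g, r in merged.items() if r == "oncogene"}
        ann.tsgs = {g for g, r in merged.items() if r == "tsg"}
    if chromosomes_path is not None:
        for line in Path(chromosomes_path).read_text().splitlines():
            if line.strip():
                g, c = line.split("\t")[:2]
                ann.chromosome_of_gene[g.strip()] = c.strip()
    return ann


def results_frame(results: Sequence[GeneTestResult]) -> pd.DataFrame:
    """Results as a DataFrame ordered by ascending p then gene symbol."""
    rows = [
        {
            "gene": r.gene,
            "class_subset": r.class_subset,
            "n_mutations": r.n_case,
            "effect_size": r.effect_size,
            "p_geomean": r.p_geomean,
            "q_value": r.q_value,
            "driver_flag": r.driver_flag,
        }
        for r in results
    ]
    df = pd.DataFrame(rows)
    return df.sort_values(["p_geomean", "gene"], kind="mergesort").reset_index(drop=True)


def write_results(results: Sequence[GeneTestResult], path: str | Path) -> Path:
    """Write results to TSV (ascending p, then gene symbol).

    Refuses to write an empty result set: an empty file would be
    indistinguishable from a truncated run.
    """
    if len(results) == 0:
        raise ValueError("no results to write")
    path = Path(path)
    df = results_frame(results)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a results TSV written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t")
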