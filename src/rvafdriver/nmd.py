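"""Nonsense-mediated decay (NMD) correction of nonsense-mutation RNA VAFs.

Transcripts carrying premature termination codons are degraded by NMD, which
depresses the apparent RNA VAF of nonsense mutations relative to missense
mutations in the same cohort.  Given an externally supplied per-mutation NMD
score (higher = stronger predicted decay), nonsense mutations are binned into
deciles of that score and each decile's mean RNA VAF is divided by the mean
missense RNA VAF, yielding a per-decile suppression factor.  Applying the
model divides a nonsense mutation's VAF by its decile factor (floored at
0.05), restoring the decay-suppressed VAF upward, capped at 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import CohortTable, VarClass

logger = logging.getLogger(__name__)

FACTOR_FLOOR = 0.05


@dataclass
class NMDModel:
    """Decile-based nonsense-VAF scaling factors.

    ``decile_edges`` holds the 11 empirical quantile boundaries of the NMD
    score among nonsense mutations; ``factor_per_decile`` the 10 suppression
    ratios (mean nonsense VAF in decile / mean missense VAF).
    ``global_factor`` (all nonsense / missense) covers mutations without a
    score and fit fallbacks.
    """

    global_factor: float
    decile_edges: np.ndarray | None = None
    factor_per_decile: np.ndarray | None = None

    @property
    def has_deciles(self) -> bool:
        return self.decile_edges is not None and self.factor_per_decile is not None

    def factor_for_score(self, score: float) -> float:
        if not self.has_deciles or score is None or np.isnan(score):
            return self.global_factor
        # right-closed last bin; clip keeps out-of-range scores in end bins
        idx = int(np.searchsorted(self.decile_edges[1:-1], score, side="right"))
        return float(self.factor_per_decile[idx])

    def to_frame(self) -> pd.DataFrame:
        if not self.has_deciles:
            return pd.DataFrame(
                {"decile": [0], "lower": [np.nan], "upper": [np.nan],
                 "factor": [self.global_factor]}
            )
        return pd.DataFrame(
            {
                "decile": np.arange(1, 11),
                "lower": self.decile_edges[:-1],
                "upper": self.decile_edges[1:],
                "factor": self.factor_per_decile,
            }
        )

    def save(self, path: str | Path) -> None:
        self.to_frame().assign(global_factor=self.global_factor).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def load(cls, path: str | Path) -> "NMDModel":
        df = pd.read_csv(path, sep="\t")
        g = float(df["global_factor"].iloc[0])
        if len(df) < 10 or df["lower"].isna().all():
            return cls(global_factor=g)
        edges = np.concatenate([df["lower"].to_numpy(), [df["upper"].iloc[-1]]])
        return cls(global_factor=g, decile_edges=edges,
                   factor_per_decile=df["factor"].to_numpy())


def fit_nmd_model(cohort: CohortTable, min_nonsense: int = 10) -> NMDModel:
    """Fit per-decile suppression factors from a weighted cohort.

    Requires ``rna_vaf``/``rna_depth`` columns (see
    :func:`rvafdriver.preprocess.compute_weights`).  Only mutations with
    positive RNA depth inform the means.  With fewer than ``min_nonsense``
    scored nonsense mutations only the global factor is fit.
    """
    df = cohort.df
    covered = df[(df["rna_alt"] + df["rna_ref"]) > 0]
    mis = covered[covered["var_class"] == VarClass.MISSENSE.value]
    non = covered[covered["var_class"] == VarClass.NONSENSE.value]
    if mis.empty or non.empty:
        logger.warning("no covered missense or nonsense mutations; NMD factor = 1")
        return NMDModel(global_factor=1.0)

    vaf = lambda d: (d["rna_alt"] / (d["rna_alt"] + d["rna_ref"])).to_numpy()
    mis_mean = float(np.mean(vaf(mis)))
    if mis_mean <= 0:
        logger.warning("missense mean RNA VAF is 0; NMD factor = 1")
        return NMDModel(global_factor=1.0)
    global_factor = float(np.mean(vaf(non))) / mis_mean

    scored = non[non["nmd_score"].notna()]
    if len(scored) < min_nonsense:
        logger.warning(
            "only %d scored nonsense mutations (<%d); using global NMD factor",
            len(scored), min_nonsense,
        )
        return NMDModel(global_factor=global_factor)

    edges = np.quantile(scored["nmd_score"].to_numpy(), np.linspace(0, 1, 11))
    # guard against ties collapsing edges: keep strictly ascending by nudging
    eps = 1e-12 + 1e-9 * (edges[-1] - edges[0] if edges[-1] > edges[0] else 1.0)
    for i in range(1, 11):
        if edges[i] <= edges[i - 1]:
            edges[i] = edges[i - 1] + eps
    idx = np.clip(np.searchsorted(edges[1:-1], scored["nmd_score"].to_numpy(),
                                  side="right"), 0, 9)
    factors = np.full(10, global_factor)
    v = vaf(scored)
    for d in range(10):
        sel = idx == d
        if sel.any():
            factors[d] = float(np.mean(v[sel])) / mis_mean
    return NMDModel(global_factor=global_factor, decile_edges=edges,
                    factor_per_decile=factors)


def scale_vaf(rna_vaf: float, nmd_score: float, model: NMDModel) -> float:
    """NMD-corrected VAF of one nonsense mutation: vaf / factor, capped at 1."""
    factor = max(model.factor_for_score(nmd_score), FACTOR_FLOOR)
    return min(1.0, rna_vaf / factor)


def apply_nmd_scaling(cohort: CohortTable, model: NMDModel) -> CohortTable:
    """Add a ``scaled_vaf`` column: NMD-corrected for nonsense mutations,
    the plain RNA VAF for everything else."""
    df = cohort.df.copy()
    if "rna_vaf" not in df:
        raise ValueError("run compute_weights before NMD scaling")
    scaled = df["rna_vaf"].to_numpy(dtype=float).copy()
    is_non = (df["var_class"] == VarClass.NONSENSE.value).to_numpy()
    scores = df["nmd_score"].to_numpy(dtype=float)
    for i in np.flatnonzero(is_non):
        scaled[i] = scale_vaf(scaled[i], scores[i], model)
    df["scaled_vaf"] = scaled
    return CohortTable(cohort.cancer_type, df)
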