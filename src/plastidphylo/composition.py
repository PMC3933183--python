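"""Compositional-bias diagnostics.

Per-taxon base (or amino-acid) composition tables by codon-position stratum,
a Pearson chi-square test of composition homogeneity across taxa, the
GC-rich / AT-rich amino-acid class fractions, and ordinary least-squares
regression of those fractions on GC content.

The chi-square test treats each taxon's state counts as a row of a
contingency table and asks whether the rows share one set of state
frequencies; gaps, '?' and ambiguity codes are excluded from the counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import Alignment, PlastidPhyloError

STRATA = ("all", "pos1", "pos2", "pos3", "no3rd")

_STATES = {
    "nt": list("ACGT"),
    "ry": list("RY"),
    "aa": list("ACDEFGHIKLMNPQRSTVWY"),
}

#: Amino acids encoded exclusively by GC-rich codons.
GC_RICH_AA = tuple("GARP")
#: Amino acids encoded exclusively by AT-rich codons.
AT_RICH_AA = tuple("FYMINK")


@dataclass
class CompositionReport:
    """Per-taxon unambiguous state counts for one stratum."""

    counts: pd.DataFrame  # index = taxa, columns = states
    stratum: str
    flagged: list[str] = field(default_factory=list)  # all-gap taxa

    @property
    def gc(self) -> pd.Series:
        """Per-taxon GC fraction (nt matrices only), gaps/ambiguities excluded."""
        if set("GC") - set(self.counts.columns):
            raise PlastidPhyloError("GC defined only for nucleotide counts")
        total = self.counts.sum(axis=1)
        return (self.counts["G"] + self.counts["C"]) / total


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p: float


def _stratum_columns(matrix: Alignment, stratum: str) -> np.ndarray:
    if stratum == "all":
        return np.arange(matrix.n_columns)
    if matrix.codon_phase is None:
        raise PlastidPhyloError(f"stratum {stratum!r} needs codon_phase")
    phase = matrix.codon_phase
    wanted = {"pos1": [1], "pos2": [2], "pos3": [3], "no3rd": [1, 2]}
    if stratum not in wanted:
        raise PlastidPhyloError(f"unknown stratum {stratum!r}")
    return np.flatnonzero(np.isin(phase, wanted[stratum]))


def composition_table(matrix: Alignment, stratum: str = "all") -> CompositionReport:
    """Count unambiguous states per taxon in the requested stratum.

    Gaps, '?' and partial ambiguity codes are excluded.  Taxa with no
    countable characters are flagged (and should be dropped before
    homogeneity testing).
    """
    cols = _stratum_columns(matrix, stratum)
    arr = matrix.to_array()[:, cols]
    states = _STATES[matrix.alphabet]
    counts = np.zeros((matrix.n_taxa, len(states)), dtype=np.int64)
    for j, s in enumerate(states):
        counts[:, j] = (arr == s.encode()).sum(axis=1)
    df = pd.DataFrame(counts, index=matrix.taxa, columns=states)
    flagged = df.index[df.sum(axis=1) == 0].tolist()
    return CompositionReport(counts=df, stratum=stratum, flagged=flagged)


def chisq_homogeneity(report: CompositionReport | pd.DataFrame) -> ChiSquareResult:
    """Pearson chi-square test of composition homogeneity across taxa.

    Expected counts are ``row_total * col_total / N``;
    ``df = (n_taxa - 1)(n_states - 1)``; the p-value is the upper tail of
    the chi-square distribution (no continuity correction).
    """
    counts = report.counts if isinstance(report, CompositionReport) else report
    obs = counts.to_numpy(dtype=float)
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        raise PlastidPhyloError("need >= 2 taxa and >= 2 states")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if (row == 0).any():
        bad = counts.index[row == 0][0]
        raise PlastidPhyloError(f"taxon {bad!r} has zero countable characters")
    if (col == 0).any():
        bad = counts.columns[col == 0][0]
        raise PlastidPhyloError(f"state {bad!r} absent from every taxon")
    expected = np.outer(row, col) / obs.sum()
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return ChiSquareResult(statistic=stat, df=df, p=float(stats.chi2.sf(stat, df)))


def aa_class_fractions(aa_matrix: Alignment) -> pd.DataFrame:
    """Per-taxon fractions of GC-rich (G,A,R,P) and AT-rich (F,Y,M,I,N,K)
    amino acids, over counted residues (X and gaps excluded)."""
    if aa_matrix.alphabet != "aa":
        raise PlastidPhyloError("amino-acid matrix required")
    rep = composition_table(aa_matrix, "all")
    total = rep.counts.sum(axis=1)
    gc_rich = rep.counts[list(GC_RICH_AA)].sum(axis=1)
    at_rich = rep.counts[list(AT_RICH_AA)].sum(axis=1)
    out = pd.DataFrame(
        {
            "gc_rich_frac": gc_rich / total,
            "at_rich_frac": at_rich / total,
        },
        index=aa_matrix.taxa,
    )
    out.loc[rep.flagged] = np.nan
    return out


@dataclass(frozen=True)
class OLSFit:
    slope: float
    intercept: float
    r_squared: float
    p_slope: float


def ols_fit(x: Sequence[float], y: Sequence[float]) -> OLSFit:
    """Ordinary least-squares fit with a two-sided t-test on the slope."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise PlastidPhyloError("need at least 3 points")
    if np.ptp(x) == 0:
        raise PlastidPhyloError("x is constant; slope undefined")
    res = stats.linregress(x, y)
    return OLSFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_slope=float(res.pvalue),
    )


def composition_summary(
    nt_matrix: Alignment,
    strata: Sequence[str] = ("all", "no3rd", "pos1", "pos2", "pos3"),
) -> pd.DataFrame:
    """Chi-square homogeneity results per stratum (Table-1-style layout)."""
    rows = []
    for stratum in strata:
        rep = composition_table(nt_matrix, stratum)
        counts = rep.counts.drop(index=rep.flagged)
        res = chisq_homogeneity(counts)
        rows.append(
            {
                "stratum": stratum,
                "chi2": res.statistic,
                "df": res.df,
                "p": res.p,
                "mean_gc": float(
                    CompositionReport(counts, stratum).gc.mean()
                ),
                "n_taxa": counts.shape[0],
            }
        )
    return pd.DataFrame(rows)
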