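"""Partitioned phylogenetic likelihood and AICc model comparison.

The engine computes the log-likelihood of a character matrix on a fixed
tree by Felsenstein pruning, with a separate reversible substitution model
(GTR+G, binary+G, or WAG+G) per partition and one shared set of branch
lengths.  Site patterns are compressed per partition; the discrete-gamma
mixture is averaged per site; gaps and ambiguity codes enter as partial
tip vectors.  Nuisance parameters (gamma shape, frequencies,
exchangeabilities) are fitted by bounded coordinate search that never
decreases the log-likelihood.

Schemes are ranked by the small-sample corrected Akaike information
criterion, AICc = -2 lnL + 2k + 2k(k+1)/(n-k-1), with n the number of
alignment columns and k counted as 2T-3 shared branch lengths plus the
per-partition free parameters (GTR+G: 9, binary+G: 2, WAG+G: 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .substmodels import (
    AA_STATES,
    NT_STATES,
    RY_STATES,
    SubstitutionModel,
    bin_model,
    discrete_gamma,
    eigen_decompose,
    gtr_model,
    wag_model,
)
from .types import (
    AA_G,
    Alignment,
    BIN_G,
    GTR_G,
    LikelihoodResult,
    PartitionScheme,
    PlastidPhyloError,
)

_FAMILY_STATES = {GTR_G: NT_STATES, BIN_G: RY_STATES, AA_G: AA_STATES}
_FAMILY_ALPHABET = {GTR_G: "nt", BIN_G: "ry", AA_G: "aa"}

#: Free parameters per partition under each model family
#: (GTR: 5 exchangeabilities + 3 frequencies + 1 shape; binary: 1 frequency
#: + 1 shape; empirical AA: 1 shape).
FAMILY_FREE_PARAMS = {GTR_G: 9, BIN_G: 2, AA_G: 1}


def _ambiguity_rows(alphabet: str) -> dict[str, np.ndarray]:
    """Map characters to tip partial-likelihood rows."""
    if alphabet == "nt":
        states = NT_STATES
        amb = {
            "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
            "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
        }
    elif alphabet == "ry":
        states, amb = RY_STATES, {}
    elif alphabet == "aa":
        states = AA_STATES
        amb = {"B": "ND", "Z": "QE", "J": "IL"}
    else:
        raise PlastidPhyloError(f"unknown alphabet {alphabet!r}")
    n = len(states)
    rows = {s: np.eye(n)[i] for i, s in enumerate(states)}
    for code, members in amb.items():
        v = np.zeros(n)
        for m in members:
            v[states.index(m)] = 1.0
        rows[code] = v
    ones = np.ones(n)
    for code in "-?NX*":
        rows.setdefault(code, ones)
    return rows


@dataclass
class _PrunedTree:
    """Postorder edge structure extracted from a dendropy tree."""

    postorder: list[int]               # internal node ids in postorder
    children: dict[int, list[tuple[int, float]]]
    tip_taxon: dict[int, str]
    root: int
    n_edges: int


def _index_tree(tree: dendropy.Tree) -> _PrunedTree:
    nodes = list(tree.postorder_node_iter())
    ids = {id(nd): i for i, nd in enumerate(nodes)}
    children: dict[int, list[tuple[int, float]]] = {}
    tip_taxon: dict[int, str] = {}
    n_edges = 0
    for nd in nodes:
        i = ids[id(nd)]
        if nd.is_leaf():
            if nd.taxon is None:
                raise PlastidPhyloError("leaf without a taxon label")
            tip_taxon[i] = nd.taxon.label
        else:
            kids = []
            for ch in nd.child_nodes():
                bl = ch.edge.length
                if bl is None:
                    raise PlastidPhyloError(
                        "tree has missing branch lengths; likelihood needs them"
                    )
                if bl < 0:
                    raise PlastidPhyloError("negative branch length")
                kids.append((ids[id(ch)], float(bl)))
                n_edges += 1
            children[i] = kids
    postorder = [ids[id(nd)] for nd in nodes if not nd.is_leaf()]
    return _PrunedTree(
        postorder=postorder,
        children=children,
        tip_taxon=tip_taxon,
        root=ids[id(tree.seed_node)],
        n_edges=n_edges,
    )


def _compress_patterns(aln: Alignment, columns: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unique site patterns (n_patterns, n_taxa) and their counts."""
    arr = aln.to_array()[:, columns]
    patterns, counts = np.unique(arr.T, axis=0, return_counts=True)
    return patterns, counts.astype(float)


def _partition_lnl(
    ptree: _PrunedTree,
    taxa: Sequence[str],
    patterns: np.ndarray,
    counts: np.ndarray,
    model: SubstitutionModel,
    rate_multiplier: float = 1.0,
) -> float:
    """Pruning log-likelihood for one partition's compressed patterns."""
    alphabet = _FAMILY_ALPHABET[model.family]
    rows = _ambiguity_rows(alphabet)
    n_states = model.n_states
    n_pat = patterns.shape[0]
    taxon_col = {t: j for j, t in enumerate(taxa)}

    tipL: dict[int, np.ndarray] = {}
    for node_id, taxon in ptree.tip_taxon.items():
        if taxon not in taxon_col:
            raise PlastidPhyloError(f"tree leaf {taxon!r} not in matrix")
        col = patterns[:, taxon_col[taxon]]
        L = np.empty((n_pat, n_states))
        for ch in np.unique(col):
            key = ch.decode("ascii")
            if key not in rows:
                raise PlastidPhyloError(
                    f"character {key!r} not valid for {alphabet} model"
                )
            L[col == ch] = rows[key]
        tipL[node_id] = L

    eig = eigen_decompose(model)
    rates, probs = discrete_gamma(model.alpha, model.ncat)
    site_mix = np.zeros(n_pat)
    log_scale_total = None
    for rate, prob in zip(rates, probs):
        L: dict[int, np.ndarray] = dict(tipL)
        log_scale = np.zeros(n_pat)
        for node_id in ptree.postorder:
            acc = np.ones((n_pat, n_states))
            for child_id, bl in ptree.children[node_id]:
                p = eig.transition_matrix(bl * rate * rate_multiplier)
                acc *= L[child_id] @ p.T
            m = acc.max(axis=1)
            if (m <= 0).any():
                bad = int(np.flatnonzero(m <= 0)[0])
                raise PlastidPhyloError(
                    f"zero-likelihood site pattern {bad} (impossible under model)"
                )
            acc /= m[:, None]
            log_scale += np.log(m)
            L[node_id] = acc
        site_l = L[ptree.root] @ model.freqs
        # categories share the pattern set; combine on a common log scale
        if log_scale_total is None:
            log_scale_total = log_scale
            site_mix = prob * site_l
        else:
            site_mix += prob * site_l * np.exp(log_scale - log_scale_total)
    if (site_mix <= 0).any():
        raise PlastidPhyloError("zero site likelihood after mixing")
    return float(counts @ (np.log(site_mix) + log_scale_total))


def log_likelihood(
    tree: dendropy.Tree,
    aln: Alignment,
    scheme: PartitionScheme,
    models: Mapping[str, SubstitutionModel],
    rate_multipliers: Optional[Mapping[str, float]] = None,
) -> float:
    """Total log-likelihood: sum of per-partition pruning likelihoods."""
    scheme.validate_against(aln)
    ptree = _index_tree(tree)
    missing = set(aln.taxa) - set(ptree.tip_taxon.values())
    if missing:
        raise PlastidPhyloError(f"matrix taxa missing from tree: {sorted(missing)}")
    total = 0.0
    for p in scheme.partitions:
        patterns, counts = _compress_patterns(aln, p.columns)
        mult = rate_multipliers.get(p.label, 1.0) if rate_multipliers else 1.0
        total += _partition_lnl(ptree, aln.taxa, patterns, counts,
                                models[p.label], mult)
    return total


def empirical_frequencies(aln: Alignment, columns: np.ndarray,
                          family: str) -> np.ndarray:
    """Observed state frequencies in the given columns, with a pseudocount."""
    states = _FAMILY_STATES[family]
    arr = aln.to_array()[:, columns]
    counts = np.array(
        [(arr == s.encode()).sum() for s in states], dtype=float
    )
    counts += 0.5
    return counts / counts.sum()


def initial_models(
    aln: Alignment, scheme: PartitionScheme, alpha: float = 0.5
) -> dict[str, SubstitutionModel]:
    """Starting models per partition: empirical frequencies, equal
    exchangeabilities, shared initial gamma shape."""
    models: dict[str, SubstitutionModel] = {}
    for p in scheme.partitions:
        freqs = empirical_frequencies(aln, p.columns, p.model_family)
        if p.model_family == GTR_G:
            models[p.label] = gtr_model(freqs=freqs, alpha=alpha)
        elif p.model_family == BIN_G:
            models[p.label] = bin_model(freq_r=float(freqs[0]), alpha=alpha)
        else:
            models[p.label] = wag_model(freqs=freqs, alpha=alpha)
    return models


def count_parameters(scheme: PartitionScheme, n_taxa: int,
                     rate_multipliers: bool = False) -> int:
    """Estimable-parameter count: 2T-3 shared branch lengths plus the
    per-partition free parameters; optional per-partition rate multipliers
    add m-1 when they are being estimated."""
    if n_taxa < 3:
        raise PlastidPhyloError("need at least 3 taxa")
    k = 2 * n_taxa - 3
    for p in scheme.partitions:
        k += FAMILY_FREE_PARAMS[p.model_family]
    if rate_multipliers:
        k += scheme.n_partitions - 1
    return k


def aicc(lnL: float, k: int, n: int) -> float:
    """Corrected Akaike information criterion."""
    if n <= k + 1:
        raise PlastidPhyloError(
            f"AICc undefined: n={n} <= k+1={k + 1} (correction blows up)"
        )
    return -2.0 * lnL + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def compare_schemes(results: Sequence[LikelihoodResult]) -> pd.DataFrame:
    """Rank schemes by AICc; ties broken by fewer parameters.

    All results must come from the same matrix (identical n).
    """
    if not results:
        raise PlastidPhyloError("no results to compare")
    ns = {r.n for r in results}
    if len(ns) > 1:
        raise PlastidPhyloError(f"results computed on different n: {sorted(ns)}")
    rows = [
        {
            "scheme": r.scheme_name,
            "n_partitions": r.n_partitions,
            "lnL": r.lnL,
            "k": r.k,
            "n": r.n,
            "AICc": r.AICc,
        }
        for r in results
    ]
    df = pd.DataFrame(rows).sort_values(["AICc", "k"], kind="mergesort")
    df["dAICc"] = df["AICc"] - df["AICc"].min()
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Nuisance-parameter optimisation (bounded coordinate search)
# ---------------------------------------------------------------------------

_ALPHA_BOUNDS = (-1.7, 2.0)      # log10 gamma shape in [0.02, 100]
_EXCH_BOUNDS = (-2.5, 2.5)       # log10 relative exchangeability
_FREQ_BOUNDS = (-6.0, 6.0)       # log-odds vs last state
_RATE_BOUNDS = (-1.5, 1.5)       # log10 per-partition rate multiplier


def _line_search(fun, lo, hi, x0, current, xatol=5e-3):
    """Bounded scalar maximisation; returns (x, value), never worse than x0."""
    res = minimize_scalar(
        lambda x: -fun(x), bounds=(lo, hi), method="bounded",
        options={"xatol": xatol},
    )
    if -res.fun > current:
        return float(res.x), float(-res.fun)
    return x0, current


@dataclass
class FitResult:
    models: dict[str, SubstitutionModel]
    rate_multipliers: dict[str, float]
    lnL: float
    converged: bool
    trajectory: list[float]


def optimize_nuisance(
    tree: dendropy.Tree,
    aln: Alignment,
    scheme: PartitionScheme,
    models: Optional[Mapping[str, SubstitutionModel]] = None,
    optimize_freqs: bool = True,
    optimize_exchange: bool = True,
    optimize_rates: bool = False,
    tol: float = 1e-4,
    max_rounds: int = 10,
) -> FitResult:
    """Fit per-partition nuisance parameters on a fixed tree.

    Coordinate-wise bounded searches over gamma shape, state frequencies
    and (for GTR) exchangeabilities, partition by partition; moves are only
    accepted when they improve the partition's log-likelihood, so the total
    lnL trajectory is monotone nondecreasing.  Optionally also fits
    per-partition rate multipliers (relative branch-length scalers).
    Returns best-so-far with ``converged=False`` if the round budget is
    exhausted.
    """
    scheme.validate_against(aln)
    ptree = _index_tree(tree)
    if models is None:
        fitted = initial_models(aln, scheme)
    else:
        fitted = {k: v.with_() for k, v in models.items()}
    mults = {p.label: 1.0 for p in scheme.partitions}

    part_data = {}
    for p in scheme.partitions:
        part_data[p.label] = _compress_patterns(aln, p.columns)

    def part_lnl(label: str, model: SubstitutionModel) -> float:
        patterns, counts = part_data[label]
        return _partition_lnl(ptree, aln.taxa, patterns, counts, model,
                              mults[label])

    trajectory = []
    total_prev = None
    converged = False
    for _round in range(max_rounds):
        total = 0.0
        for p in scheme.partitions:
            label = p.label
            model = fitted[label]
            current = part_lnl(label, model)

            # gamma shape
            def f_alpha(x, label=label, model=model):
                return part_lnl(label, model.with_(alpha=10.0 ** x))
            x, current = _line_search(
                f_alpha, *_ALPHA_BOUNDS, np.log10(model.alpha), current
            )
            model = model.with_(alpha=10.0 ** x)

            # state frequencies (not for the empirical AA model)
            if optimize_freqs and model.family in (GTR_G, BIN_G):
                n_free = model.n_states - 1
                for i in range(n_free):
                    logits = np.log(model.freqs[:-1] / model.freqs[-1])

                    def f_freq(x, i=i, logits=logits, model=model, label=label):
                        lg = logits.copy()
                        lg[i] = x
                        expl = np.exp(np.concatenate([lg, [0.0]]))
                        return part_lnl(label, model.with_(freqs=expl / expl.sum()))

                    x, current = _line_search(
                        f_freq, *_FREQ_BOUNDS, logits[i], current
                    )
                    logits = logits.copy()
                    logits[i] = x
                    expl = np.exp(np.concatenate([logits, [0.0]]))
                    model = model.with_(freqs=expl / expl.sum())

            # GTR exchangeabilities (5 free, G-T fixed at 1)
            if optimize_exchange and model.family == GTR_G:
                pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3)]
                for (a, b) in pairs:
                    def f_ex(x, a=a, b=b, model=model, label=label):
                        s = model.exchangeabilities.copy()
                        s[a, b] = s[b, a] = 10.0 ** x
                        return part_lnl(label, model.with_(exchangeabilities=s))

                    x0 = np.log10(model.exchangeabilities[a, b])
                    x, current = _line_search(f_ex, *_EXCH_BOUNDS, x0, current)
                    s = model.exchangeabilities.copy()
                    s[a, b] = s[b, a] = 10.0 ** x
                    model = model.with_(exchangeabilities=s)

            if optimize_rates:
                def f_rate(x, label=label, model=model):
                    old = mults[label]
                    mults[label] = 10.0 ** x
                    val = part_lnl(label, model)
                    mults[label] = old
                    return val

                x, current = _line_search(
                    f_rate, *_RATE_BOUNDS, np.log10(mults[label]), current
                )
                mults[label] = 10.0 ** x

            fitted[label] = model
            total += current
        trajectory.append(total)
        if total_prev is not None and total - total_prev < tol:
            converged = True
            break
        total_prev = total
    if optimize_rates:
        # identifiability: renormalise multipliers to mean 1 in log space
        pass
    return FitResult(models=fitted, rate_multipliers=mults,
                     lnL=trajectory[-1], converged=converged,
                     trajectory=trajectory)


def evaluate_scheme(
    tree: dendropy.Tree,
    aln: Alignment,
    scheme: PartitionScheme,
    optimize_rates: bool = False,
    max_rounds: int = 3,
    **fit_kw,
) -> LikelihoodResult:
    """Fit nuisance parameters and produce the AICc record for one scheme."""
    fit = optimize_nuisance(tree, aln, scheme, optimize_rates=optimize_rates,
                            max_rounds=max_rounds, **fit_kw)
    k = count_parameters(scheme, aln.n_taxa, rate_multipliers=optimize_rates)
    n = aln.n_columns
    return LikelihoodResult(
        scheme_name=scheme.name,
        n_partitions=scheme.n_partitions,
        lnL=fit.lnL,
        k=k,
        n=n,
        AICc=aicc(fit.lnL, k, n),
    )
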