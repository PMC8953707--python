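"""Stage 1: gene-pair inference from expression matrices.

Two complementary extractors over a genes x samples matrix:

* :func:`pearson_pairs` — all unordered gene pairs whose two-sided Pearson
  p-value (t transform of r with n-2 degrees of freedom) falls below a
  threshold; with the default 5e-7 this matches an |r| >= 0.9 cutoff at the
  sample size returned by :func:`equivalence_sample_size`.
* :func:`iamb_markov_blanket` — the incremental-association Markov blanket
  (parents, children and spouses) of a target gene, recovered by the
  grow/shrink procedure with a partial-correlation Fisher-z conditional
  independence test, the standard continuous-data instantiation.

:func:`combine_pair_lists` merges the two into the single regulator list
handed to knowledge-graph construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

PAIR_COLUMNS = ["gene_a", "gene_b", "r", "p", "source"]

DEFAULT_P_THRESHOLD = 5e-7


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples expression TSV (gene ids in the first column)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression_tsv(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene_id")


def _validate_expression(expr: pd.DataFrame) -> None:
    if expr.shape[1] < 3:
        raise ValueError("expression matrix needs at least 3 samples")
    if expr.index.has_duplicates:
        raise ValueError("gene ids must be unique")
    if expr.isna().any().any():
        raise ValueError("expression matrix contains missing values")


def pearson_p_value(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p-value of a Pearson correlation via the t transform
    ``t = r sqrt((n-2)/(1-r^2))`` with n-2 degrees of freedom."""
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, np.finfo(float).tiny))
    return 2.0 * stats.t.sf(np.abs(t), df=n - 2)


def equivalence_sample_size(
    r_threshold: float = 0.9, p_threshold: float = DEFAULT_P_THRESHOLD, n_max: int = 1000
) -> int:
    """Sample size at which the p-value cutoff and the |r| cutoff coincide.

    For each n the p-threshold corresponds to an |r| cutoff
    ``r_c(n) = t_c / sqrt(n-2+t_c^2)`` with ``t_c`` the upper p/2 t-quantile;
    returns the n whose r_c is closest to ``r_threshold`` (r_c is monotone
    decreasing in n, so this is where the two selections agree).
    """
    best_n, best_gap = None, np.inf
    for n in range(4, n_max + 1):
        tc = stats.t.isf(p_threshold / 2.0, df=n - 2)
        rc = tc / np.sqrt(n - 2 + tc**2)
        gap = abs(rc - r_threshold)
        if gap < best_gap:
            best_n, best_gap = n, gap
        elif rc < r_threshold and gap > best_gap:
            break
    return int(best_n)


def pearson_pairs(
    expr: pd.DataFrame,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    r_threshold: float | None = None,
) -> pd.DataFrame:
    """All unordered gene pairs passing the correlation significance cutoff.

    Selection is ``p < p_threshold`` (two-sided, so strong negative
    correlation qualifies too); pass ``r_threshold`` instead to select on
    ``|r| >= r_threshold``.  Zero-variance genes are skipped and logged.
    Pairs are stored canonically (gene_a < gene_b) and sorted.
    """
    _validate_expression(expr)
    if r_threshold is None and not 0 < p_threshold < 1:
        raise ValueError("p_threshold must be in (0,1)")
    n = expr.shape[1]
    values = expr.to_numpy(dtype=float)
    sd = values.std(axis=1)
    keep = sd > 0
    dropped = expr.index[~keep].tolist()
    if dropped:
        logger.warning("skipping %d zero-variance genes: %s", len(dropped), dropped[:5])
    genes = expr.index[keep].tolist()
    if len(genes) < 2:
        return pd.DataFrame(columns=PAIR_COLUMNS)
    r = np.corrcoef(values[keep])
    iu, ju = np.triu_indices(len(genes), k=1)
    rv = r[iu, ju]
    pv = pearson_p_value(rv, n)
    mask = (np.abs(rv) >= r_threshold) if r_threshold is not None else (pv < p_threshold)
    rows = []
    for i, j, rr, pp in zip(iu[mask], ju[mask], rv[mask], pv[mask]):
        a, b = sorted((genes[i], genes[j]))
        rows.append({"gene_a": a, "gene_b": b, "r": float(rr), "p": float(pp), "source": "pearson"})
    out = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    return out.sort_values(["gene_a", "gene_b"], ignore_index=True)


# ---------------------------------------------------------------------------
# IAMB Markov-blanket recovery
# ---------------------------------------------------------------------------

@dataclass
class MarkovBlanketResult:
    """Recovered Markov blanket MB(target): parents, children and spouses."""

    target: str
    blanket: set[str]
    alpha: float

    def __post_init__(self) -> None:
        if self.target in self.blanket:
            raise ValueError("target cannot be a member of its own blanket")


def fisher_z_partial_correlation(
    corr: np.ndarray, n: int, x: int, y: int, cond: tuple[int, ...] = ()
) -> tuple[float, float]:
    """Partial correlation of variables x, y given ``cond`` and its Fisher-z
    two-sided p-value at sample size n.

    The partial correlation comes from the inverse of the correlation
    submatrix over {x, y} ∪ cond; the z statistic is
    ``atanh(r) sqrt(n - |cond| - 3)``.
    """
    if n - len(cond) - 3 <= 0:
        raise ValueError("sample size too small for this conditioning set")
    idx = [x, y, *cond]
    sub = corr[np.ix_(idx, idx)]
    prec = np.linalg.pinv(sub)
    denom = np.sqrt(prec[0, 0] * prec[1, 1])
    r = 0.0 if denom == 0 else float(-prec[0, 1] / denom)
    r = float(np.clip(r, -0.999999, 0.999999))
    z = np.arctanh(r) * np.sqrt(n - len(cond) - 3)
    p = 2.0 * stats.norm.sf(abs(z))
    return r, float(p)


def iamb_markov_blanket(
    expr: pd.DataFrame, target: str, alpha: float = 0.01
) -> MarkovBlanketResult:
    """Grow/shrink recovery of MB(target) from an expression matrix.

    Grow: repeatedly add the candidate with the strongest significant
    conditional dependence on the target given the current blanket (largest
    |z|, i.e. smallest p below ``alpha``) until none qualifies.  Shrink:
    remove any member that is independent of the target given the rest.
    Constant genes are excluded; a constant target yields an empty blanket
    with a warning.
    """
    _validate_expression(expr)
    if target not in expr.index:
        raise KeyError(f"unknown target gene {target!r}")
    n = expr.shape[1]
    values = expr.to_numpy(dtype=float)
    sd = values.std(axis=1)
    if sd[expr.index.get_loc(target)] == 0:
        logger.warning("target %r is constant; returning empty blanket", target)
        return MarkovBlanketResult(target=target, blanket=set(), alpha=alpha)
    keep = sd > 0
    genes = expr.index[keep].tolist()
    corr = np.corrcoef(values[keep])
    pos = {g: i for i, g in enumerate(genes)}
    t = pos[target]
    candidates = [g for g in genes if g != target]
    max_cond = n - 4  # Fisher z requires n - |cond| - 3 >= 1

    blanket: list[str] = []
    # grow phase
    while True:
        if len(blanket) >= max_cond:
            break
        cond = tuple(pos[g] for g in blanket)
        best_gene, best_p = None, None
        for g in sorted(set(candidates) - set(blanket)):
            _, p = fisher_z_partial_correlation(corr, n, t, pos[g], cond)
            if p < alpha and (best_p is None or p < best_p):
                best_gene, best_p = g, p
        if best_gene is None:
            break
        blanket.append(best_gene)
    # shrink phase
    changed = True
    while changed:
        changed = False
        for g in sorted(blanket):
            rest = tuple(pos[h] for h in blanket if h != g)
            _, p = fisher_z_partial_correlation(corr, n, t, pos[g], rest)
            if p >= alpha:
                blanket.remove(g)
                changed = True
    return MarkovBlanketResult(target=target, blanket=set(blanket), alpha=alpha)


def markov_blankets(
    expr: pd.DataFrame, targets: list[str] | None = None, alpha: float = 0.01
) -> list[MarkovBlanketResult]:
    """IAMB blanket for each target (default: every gene in the matrix)."""
    targets = list(expr.index) if targets is None else targets
    return [iamb_markov_blanket(expr, t, alpha=alpha) for t in targets]


def combine_pair_lists(
    pearson: pd.DataFrame, blankets: list[MarkovBlanketResult]
) -> pd.DataFrame:
    """Union of Pearson pairs and (target, blanket member) pairs.

    Duplicates collapse to a single canonical record whose ``source`` field
    carries the comma-joined sorted set of originating methods; r/p are kept
    from the Pearson record where available.
    """
    records: dict[tuple[str, str], dict] = {}
    for row in pearson.itertuples(index=False):
        key = tuple(sorted((row.gene_a, row.gene_b)))
        records[key] = {
            "gene_a": key[0],
            "gene_b": key[1],
            "r": row.r,
            "p": row.p,
            "source": {"pearson"},
        }
    for res in blankets:
        for member in sorted(res.blanket):
            key = tuple(sorted((res.target, member)))
            if key in records:
                records[key]["source"].add("markov_blanket")
            else:
                records[key] = {
                    "gene_a": key[0],
                    "gene_b": key[1],
                    "r": np.nan,
                    "p": np.nan,
                    "source": {"markov_blanket"},
                }
    rows = [
        {**rec, "source": ",".join(sorted(rec["source"]))}
        for key, rec in sorted(records.items())
    ]
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def write_pairs_tsv(pairs: pd.DataFrame, path: str | Path) -> None:
    pairs.to_csv(path, sep="\t", index=False)
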