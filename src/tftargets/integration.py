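"""Integration of the three evidence layers into primary-target calls.

A transcript is a *primary target* of the driver transcription factor in a
given condition when it (i) correlates with the driver's timecourse
expression pattern (Spearman, raw P below a cutoff, default 0.001), (ii) is
differentially expressed on driver knockdown at 5% FDR, and (iii) carries a
binding peak linked to it. Direction follows the knockdown fold-change
sign: positive (higher in scrambled control) means the driver activates the
gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .util import round_half_up

log = logging.getLogger(__name__)

RING_CATEGORIES = ("correlated_only", "peak", "down_regulated", "up_regulated")


@dataclass(frozen=True)
class PrimaryTarget:
    gene_id: str
    condition: str
    direction: str  # activated | repressed
    rho: float
    sirna_fc: float
    peak_ids: tuple[str, ...]


def driver_correlation(expr: pd.DataFrame, driver_gene: str,
                       mean_profile: bool = False,
                       sample_meta: Optional[pd.DataFrame] = None
                       ) -> pd.DataFrame:
    """Spearman correlation of every transcript with the driver's profile.

    The driver's values over all samples (both strains, all timepoints, all
    replicates, in the matrix column order) form the reference vector; each
    transcript's rho and two-sided P (t approximation, average ranks for
    ties) are returned. With ``mean_profile=True`` samples are first
    averaged within (strain, timepoint) groups of ``sample_meta``.
    Constant transcripts get missing rho/p.
    """
    if driver_gene not in expr.index:
        raise KeyError(f"driver gene {driver_gene!r} not in expression matrix")
    if mean_profile:
        if sample_meta is None:
            raise ValueError("mean_profile requires sample_meta")
        groups = sample_meta.set_index("sample_id").loc[expr.columns]
        key = list(zip(groups["strain"], groups["timepoint"]))
        expr = expr.T.groupby(pd.Index(key).map(str)).mean().T
    X = expr.to_numpy(dtype=float)
    n = X.shape[1]
    if n < 8:
        raise ValueError("need >= 8 samples for the correlation screen")
    ranks = stats.rankdata(X, axis=1)
    driver_ranks = ranks[expr.index.get_loc(driver_gene)]
    rz = ranks - ranks.mean(axis=1, keepdims=True)
    dz = driver_ranks - driver_ranks.mean()
    denom = np.sqrt((rz**2).sum(axis=1) * (dz**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (rz @ dz) / denom
    rho[denom == 0] = np.nan
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isnan(rho), np.nan, np.where(np.abs(rho) >= 1.0, 0.0, p))
    p = np.where(np.isnan(p), np.nan, np.minimum(p, 1.0))
    out = pd.DataFrame({"rho": rho, "p": p}, index=expr.index)
    out["q_bh"] = np.nan
    ok = out["p"].notna()
    if ok.any():
        from statsmodels.stats.multitest import multipletests
        out.loc[ok, "q_bh"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    return out


def select_correlated(results: pd.DataFrame, driver_gene: str,
                      p_cut: float = 0.001) -> set[str]:
    """Transcripts with raw P strictly below ``p_cut``, excluding the driver."""
    sel = results.index[(results["p"] < p_cut) & results["p"].notna()]
    return set(sel) - {driver_gene}


def call_primary_targets(correlated: set[str], sirna_de: pd.DataFrame,
                         linked_genes: Mapping[str, Sequence[str]],
                         condition: str,
                         corr: Optional[pd.DataFrame] = None,
                         de_condition: Optional[str] = None,
                         peaks_condition: Optional[str] = None
                         ) -> list[PrimaryTarget]:
    """Conjunction of the three evidence layers for one condition.

    ``sirna_de`` is a two-group DE result table (index gene_id, columns
    fold_change / called); ``linked_genes`` maps gene id to its peak ids.
    The optional ``de_condition`` / ``peaks_condition`` tags guard against
    mixing evidence from different conditions.
    """
    for tag, name in ((de_condition, "siRNA DE"), (peaks_condition, "peak")):
        if tag is not None and tag != condition:
            raise ValueError(f"{name} input is from condition {tag!r}, expected {condition!r}")
    called = set(sirna_de.index[sirna_de["called"].astype(bool)])
    hits = sorted(correlated & called & set(linked_genes))
    targets = []
    for g in hits:
        fc = float(sirna_de.loc[g, "fold_change"])
        targets.append(PrimaryTarget(
            gene_id=g, condition=condition,
            direction="activated" if fc > 0 else "repressed",
            rho=float(corr.loc[g, "rho"]) if corr is not None else np.nan,
            sirna_fc=fc, peak_ids=tuple(linked_genes[g])))
    return targets


def ring_summary(correlated: set[str], linked_genes: Mapping[str, Sequence[str]],
                 sirna_de: pd.DataFrame) -> pd.DataFrame:
    """Partition correlated transcripts into the four ring categories.

    Priority: down-regulated on knockdown > up-regulated > peak-associated >
    correlated-only, so each transcript lands in exactly one category.
    Percentages (of the partition total) are reported both at one decimal
    and rounded half-up to integers.
    """
    called = sirna_de["called"].astype(bool)
    down = set(sirna_de.index[called & (sirna_de["fold_change"] > 0)])
    up = set(sirna_de.index[called & (sirna_de["fold_change"] <= 0)])
    counts = dict.fromkeys(RING_CATEGORIES, 0)
    for g in correlated:
        if g in down:
            counts["down_regulated"] += 1
        elif g in up:
            counts["up_regulated"] += 1
        elif g in linked_genes:
            counts["peak"] += 1
        else:
            counts["correlated_only"] += 1
    return ring_summary_from_counts(counts)


def ring_summary_from_counts(counts: Mapping[str, int]) -> pd.DataFrame:
    """Counts plus percentages for the four ring categories."""
    total = sum(counts.values())
    rows = []
    for cat in RING_CATEGORIES:
        n = counts.get(cat, 0)
        pct = 100.0 * n / total if total else 0.0
        rows.append({"category": cat, "count": n,
                     "pct": round_half_up(pct, 1) if total else 0.0,
                     "pct_int": int(round_half_up(pct, 0)) if total else 0})
    return pd.DataFrame(rows).set_index("category")


def build_network(targets: Iterable[PrimaryTarget], driver: str) -> nx.DiGraph:
    """Star graph: the driver plus one node per target, edges carrying
    direction, correlation and knockdown fold change."""
    g = nx.DiGraph()
    g.add_node(driver, role="driver")
    seen = set()
    for t in targets:
        if t.gene_id in seen:
            log.warning("duplicate target node %s dropped", t.gene_id)
            continue
        seen.add(t.gene_id)
        g.add_node(t.gene_id, role="target", direction=t.direction)
        g.add_edge(driver, t.gene_id, direction=t.direction,
                   rho=float(t.rho), sirna_fc=float(t.sirna_fc))
    return g


def write_sif(graph: nx.DiGraph, path) -> None:
    """Simple interaction format: one `driver <direction> target` line per edge."""
    with open(path, "w") as fh:
        for u, v, data in sorted(graph.edges(data=True)):
            fh.write(f"{u}\t{data.get('direction', 'regulates')}\t{v}\n")


def write_graphml(graph: nx.DiGraph, path) -> None:
    nx.write_graphml(graph, path)
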