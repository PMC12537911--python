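"""Expansion-signature derivation, expression-matched scoring, and enrichment.

The signature is the set of genes overexpressed (Wilcoxon rank-sum,
BH-adjusted) in precursor exhausted cells of expanding clones over
contracting clones, with mitochondrial and ribosomal genes excluded.
Units (cells or bulk samples) are scored as the mean normalized expression
of signature genes minus the mean of control genes drawn from matching
average-expression bins, so the score is centred at zero for an
expression-matched random gene set and invariant to per-unit shifts.
Clone-level scores average cell scores within a state (precursor by
default) or weight state means by the clone's state composition.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ClonetrackError

logger = logging.getLogger(__name__)

#: prefixes excluded from signatures (mouse and human mito/ribosomal symbols)
DEFAULT_EXCLUSIONS = ("mt-", "Rps", "Rpl", "Mrps", "Mrpl")


def normalize_log(adata: ad.AnnData, target_sum: float = 1e4) -> ad.AnnData:
    """Depth-normalize each cell to ``target_sum`` counts, then log1p.

    Zero-depth cells are dropped with a warning.  Returns a new AnnData
    with dense float X; raw counts are left untouched in the input.
    """
    x = adata.X
    x = x.toarray() if sp.issparse(x) else np.asarray(x, dtype=float)
    if (x < 0).any():
        raise ValueError("counts must be nonnegative")
    depth = x.sum(axis=1)
    keep = depth > 0
    if not keep.all():
        logger.warning("dropping %d zero-depth cells", int((~keep).sum()))
    x = x[keep]
    norm = np.log1p(x / depth[keep][:, None] * target_sum)
    out = ad.AnnData(X=norm, obs=adata.obs.iloc[np.flatnonzero(keep)].copy())
    out.var_names = adata.var_names
    return out


def rank_sum_deg(
    norm: ad.AnnData,
    group_a: np.ndarray | Sequence[str],
    group_b: np.ndarray | Sequence[str],
) -> pd.DataFrame:
    """Per-gene two-sided Wilcoxon rank-sum test of group A vs group B.

    Groups are boolean masks over cells or lists of cell names, each with
    at least 2 cells.  Small untied groups use the exact null distribution;
    otherwise the tie-corrected normal approximation applies.  Returns a
    DEG table with per-gene log2 fold-change (difference of mean log values
    over log 2), U statistic, p, BH-adjusted p and direction.
    """
    mask_a = _as_mask(norm, group_a)
    mask_b = _as_mask(norm, group_b)
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ClonetrackError("each group needs at least 2 cells")
    xa = np.asarray(norm.X[mask_a])
    xb = np.asarray(norm.X[mask_b])
    res = stats.mannwhitneyu(xa, xb, axis=0, alternative="two-sided", method="auto")
    mean_a = xa.mean(axis=0)
    mean_b = xb.mean(axis=0)
    lfc = (mean_a - mean_b) / np.log(2.0)
    padj = multipletests(res.pvalue, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "log2fc": lfc,
            "statistic": res.statistic,
            "p_value": res.pvalue,
            "p_adj": padj,
            "direction": np.where(mean_a >= mean_b, "up", "down"),
        },
        index=pd.Index(norm.var_names, name="gene"),
    )


def _as_mask(adata: ad.AnnData, group) -> np.ndarray:
    group = np.asarray(group)
    if group.dtype == bool:
        return group
    return adata.obs_names.isin(group)


@dataclass
class GeneSignature:
    """Ordered gene list with a record of how it was derived."""

    name: str
    genes: list[str]
    species: str = "mouse"
    derivation: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("signature contains duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"gene": self.genes, "weight": 1}).to_csv(path, sep="\t", index=False)
        sidecar = Path(path).with_suffix(".json")
        sidecar.write_text(json.dumps({"name": self.name, "species": self.species,
                                       "derivation": self.derivation}))

    @classmethod
    def from_tsv(cls, path: str | Path, name: str | None = None) -> "GeneSignature":
        df = pd.read_csv(path, sep="\t")
        sidecar = Path(path).with_suffix(".json")
        meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        return cls(
            name=name or meta.get("name", Path(path).stem),
            genes=df["gene"].astype(str).tolist(),
            species=meta.get("species", "mouse"),
            derivation=meta.get("derivation", {}),
        )


def build_signature(
    deg_table: pd.DataFrame,
    alpha: float = 0.05,
    exclusions: Sequence[str] = DEFAULT_EXCLUSIONS,
    name: str = "expansion",
    species: str = "mouse",
) -> GeneSignature:
    """Overexpressed genes at adjusted p < alpha, minus mito/ribosomal genes.

    Exclusion patterns are case-insensitive gene-symbol prefixes, so the
    mouse defaults also match their uppercased human orthologs.  Genes are
    ordered by ascending adjusted p.  An empty result is a warning, not an
    error.
    """
    hits = deg_table[(deg_table["direction"] == "up") & (deg_table["p_adj"] < alpha)]
    hits = hits.sort_values(["p_adj", "p_value"], kind="mergesort")
    lowered = tuple(p.lower() for p in exclusions)
    genes = [g for g in hits.index if not str(g).lower().startswith(lowered)]
    if not genes:
        logger.warning("signature %r is empty at alpha=%g", name, alpha)
    return GeneSignature(
        name=name,
        genes=genes,
        species=species,
        derivation={"alpha": alpha, "exclusions": list(exclusions),
                    "n_overexpressed": int(len(hits)), "n_excluded": int(len(hits) - len(genes))},
    )


@dataclass
class ScoreVector:
    """Per-unit signature scores with the control-gene bookkeeping."""

    scores: pd.Series
    signature: str
    n_bins: int
    ctrl_size: int
    seed: int
    control_genes: list[str] = field(default_factory=list)
    missing_genes: list[str] = field(default_factory=list)


def score_units(
    norm: ad.AnnData,
    signature: GeneSignature,
    n_bins: int = 25,
    ctrl_size: int = 50,
    seed: int = 0,
) -> ScoreVector:
    """Expression-matched signature score per unit (cell or bulk sample).

    Genes are ranked by dataset-mean normalized expression and cut into
    ``n_bins`` equal-size bins; for each signature gene, ``ctrl_size``
    control genes are sampled (seeded, without replacement) from its bin,
    excluding signature genes.  The score is mean(signature) minus
    mean(control union), which cancels any per-unit additive shift.
    Signature genes absent from the matrix are dropped with a warning.
    """
    var_names = list(norm.var_names)
    present = [g for g in signature.genes if g in set(var_names)]
    missing = [g for g in signature.genes if g not in set(var_names)]
    if missing:
        logger.warning("%d signature genes absent from matrix", len(missing))
    if not present:
        raise ClonetrackError(f"signature {signature.name!r} entirely absent from matrix")

    x = norm.X
    x = x.toarray() if sp.issparse(x) else np.asarray(x, dtype=float)
    gene_mean = x.mean(axis=0)
    order = np.argsort(gene_mean, kind="mergesort")
    n_genes = len(var_names)
    bins = np.empty(n_genes, dtype=int)
    for b, chunk in enumerate(np.array_split(order, n_bins)):
        bins[chunk] = b

    name_to_idx = {g: i for i, g in enumerate(var_names)}
    sig_idx = np.array([name_to_idx[g] for g in present])
    sig_set = set(sig_idx.tolist())
    rng = np.random.default_rng(seed)
    ctrl: set[int] = set()
    for gi in sig_idx:
        pool = np.flatnonzero(bins == bins[gi])
        pool = np.array([i for i in pool if i not in sig_set])
        if len(pool) == 0:
            continue
        take = min(ctrl_size, len(pool))
        ctrl.update(rng.choice(pool, size=take, replace=False).tolist())
    if not ctrl:
        raise ClonetrackError("no control genes available outside the signature")
    ctrl_idx = np.array(sorted(ctrl))
    scores = x[:, sig_idx].mean(axis=1) - x[:, ctrl_idx].mean(axis=1)
    return ScoreVector(
        scores=pd.Series(scores, index=norm.obs_names, name=f"{signature.name}_score"),
        signature=signature.name,
        n_bins=n_bins,
        ctrl_size=ctrl_size,
        seed=seed,
        control_genes=[var_names[i] for i in ctrl_idx],
        missing_genes=missing,
    )


def exclude_overlap(tested: GeneSignature, reference: GeneSignature) -> GeneSignature:
    """Remove reference genes from a tested signature (order preserved).

    Used before scoring other published signatures so shared genes cannot
    inflate the correlation with the reference signature's score.
    """
    ref = set(reference.genes)
    genes = [g for g in tested.genes if g not in ref]
    if not genes:
        logger.warning("signature %r is empty after overlap exclusion", tested.name)
    return GeneSignature(
        name=tested.name,
        genes=genes,
        species=tested.species,
        derivation={**tested.derivation, "excluded_overlap_with": reference.name},
    )


def clone_mean_score(
    scores: pd.Series,
    cells: pd.DataFrame,
    clone_key,
    day: int,
    state: str = "precursor",
    min_cells: int = 5,
) -> float:
    """Mean score over a clone's cells of one state on one day.

    Returns nan (undefined) when fewer than ``min_cells`` qualifying cells
    exist; the floor guards against noisy single-cell averages.
    """
    sel = cells[
        (cells["clone_key"] == clone_key)
        & (cells["day"] == day)
        & (cells["state"] == state)
        & (cells["link_status"] == "linked")
    ]
    if len(sel) < min_cells:
        return float("nan")
    return float(scores.reindex(sel["cell_id"]).mean())


def clone_state_mean_scores(
    scores: pd.Series,
    cells: pd.DataFrame,
    day: int,
    min_cells: int = 1,
    merge_proliferating: bool = True,
) -> pd.DataFrame:
    """Per-clone mean score in each exhausted state on one day.

    Proliferating cells are folded into the terminal state (the
    proliferating cluster is predominantly terminally exhausted).  States
    with fewer than ``min_cells`` cells for a clone are nan.
    """
    sel = cells[(cells["day"] == day) & (cells["link_status"] == "linked")].copy()
    if merge_proliferating:
        sel.loc[sel["state"] == "proliferating", "state"] = "terminal"
    sel = sel[sel["state"].isin(["precursor", "intermediate", "terminal"])]
    sel["score"] = scores.reindex(sel["cell_id"]).to_numpy()
    grouped = sel.groupby(["clone_key", "state"])["score"].agg(["mean", "count"])
    mean = grouped["mean"].where(grouped["count"] >= min_cells)
    return mean.unstack("state").reindex(columns=["precursor", "intermediate", "terminal"])


def weighted_clone_score(
    state_means: Mapping[str, float] | pd.Series,
    composition: Mapping[str, float] | pd.Series,
) -> float:
    """State-composition-weighted clone score.

    Weights are the clone's (precursor, intermediate, terminal) composition
    renormalized over the PD-1+ states; a state with nonzero weight but no
    scored cells makes the score undefined (nan).  Approximates how the
    clone would score in a dataset not enriched for any one state.
    """
    states = ("precursor", "intermediate", "terminal")
    w = np.array([float(composition.get(s, 0.0)) for s in states])
    if w.sum() <= 0:
        raise ClonetrackError("composition has no weight on PD-1+ states")
    w = w / w.sum()
    total = 0.0
    for wi, s in zip(w, states):
        if wi == 0:
            continue
        m = state_means.get(s, float("nan")) if hasattr(state_means, "get") else state_means[s]
        m = float(m) if m is not None else float("nan")
        if np.isnan(m):
            return float("nan")
        total += wi * m
    return float(total)


def gsea_enrichment(
    ranked: pd.Series,
    signature: GeneSignature,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Classic weighted (exponent 1) GSEA enrichment score with permutation p.

    ``ranked`` maps every gene in the universe to a real-valued ranking
    statistic (sorted internally, descending).  The running sum increments
    by |stat|/sum(|stat| in signature) at signature genes and decrements by
    1/(N - |S|) elsewhere; ES is the maximum deviation from zero.  The p
    value resamples ``n_perm`` random gene sets of equal size and is
    two-sided on permutations matching the observed sign.
    """
    missing = [g for g in signature.genes if g not in ranked.index]
    if missing:
        raise ClonetrackError(f"{len(missing)} signature genes not in ranked universe")
    ranked = ranked.sort_values(ascending=False, kind="mergesort")
    stats_abs = np.abs(ranked.to_numpy(dtype=float))
    is_hit = ranked.index.isin(signature.genes)

    def running_es(hit_mask: np.ndarray) -> float:
        hit_w = stats_abs * hit_mask
        denom = hit_w.sum()
        if denom == 0:
            hit_w = hit_mask.astype(float)
            denom = hit_w.sum()
        n_miss = len(hit_mask) - int(hit_mask.sum())
        steps = np.where(hit_mask, hit_w / denom, -1.0 / max(n_miss, 1))
        path = np.cumsum(steps)
        return float(path[np.argmax(np.abs(path))])

    es = running_es(is_hit)
    rng = np.random.default_rng(seed)
    n = len(ranked)
    k = int(is_hit.sum())
    same_sign = 0
    matches = 0
    for _ in range(n_perm):
        perm = np.zeros(n, dtype=bool)
        perm[rng.choice(n, size=k, replace=False)] = True
        es_p = running_es(perm)
        if np.sign(es_p) == np.sign(es) or es == 0:
            same_sign += 1
            if abs(es_p) >= abs(es):
                matches += 1
    p_one = (1 + matches) / (1 + same_sign)
    return es, float(min(1.0, 2.0 * p_one))
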