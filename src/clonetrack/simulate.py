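"""Synthetic cohort generator.

Emulates the data structure of a multi-site tumor clone-tracking study:
bilateral tumor repertoires sharing a latent clone-frequency vector per
timepoint, heavy-tailed clone sizes, latent per-clone expansion rates that
move frequencies between timepoints, exhaustion-state compositions that
shift with expansion, single-cell expression with planted expansion-coupled
genes in precursor cells, and survival times whose hazard is coupled to a
subject-level score.  The latent truth is returned alongside the data so
recovery tests can compare estimates against it.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CLONE_KEY_COLS, ClonetrackError, RepertoireSample

STATE_FRACTIONS = ("PD1neg", "precursor", "intermediate", "terminal")


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults emulate the study conditions: ~400 trackable clones per mouse,
    1e5 reads per bulk repertoire, near-identical bilateral repertoires,
    clone expansion rates of a few log2 units per week, exhaustion-state
    flux tied to the expansion rate, and a planted expansion signature whose
    expression in precursor cells scales with the latent rate.
    """

    n_clones: int = 400
    clone_size_law: str = "lognormal"  # or "power"
    clone_size_mu: float = 0.0
    clone_size_sigma: float = 2.0
    clone_size_alpha: float = 2.0  # power-law exponent when clone_size_law="power"
    n_reads_per_sample: int = 100_000
    bilateral_noise_rho: float = 1e-5  # beta-binomial overdispersion between replicate tumors
    expansion_mu: float = 0.0  # log2 units per sampling interval
    expansion_sigma: float = 1.5
    days: tuple[int, ...] = (14, 21)
    # state composition: Dirichlet baseline over (PD1neg, pre, int, term),
    # tilted by expansion rate, then moved by the differentiation flux
    composition_alpha: tuple[float, float, float, float] = (2.0, 6.0, 4.0, 4.0)
    composition_E_coupling: float = 0.3  # log2 tilt of pre vs term per unit E
    flux_per_log2: float = 0.08  # precursor -> terminal per unit positive E
    regression_per_log2: float = 0.08  # terminal -> precursor per unit negative E
    # single-cell expression
    n_signature_genes: int = 30
    n_decoy_excluded_genes: int = 8  # planted genes with mito/ribo names
    n_background_genes: int = 970
    signature_effect: float = 0.3  # log2 shift per unit E in precursor cells
    signature_effect_other_states: float = 0.5  # relative effect outside precursors
    library_size_mean: float = 1500.0
    library_size_sigma: float = 0.3
    cells_per_clone: int = 20
    precursor_enrichment: float = 2.0  # sorting enrichment of precursor cells
    aliquot_fraction: float = 0.1  # cells removed from sorted fractions for sc-seq
    # survival
    baseline_hazard: float = 0.05
    hazard_beta: float = -1.0  # log-hazard per unit subject score
    censor_rate: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clones < 1 or self.n_reads_per_sample < 1:
            raise ValueError("n_clones and n_reads_per_sample must be positive")
        if not (0 <= self.bilateral_noise_rho < 1):
            raise ValueError("bilateral_noise_rho must be in [0, 1)")
        if not (0 <= self.censor_rate <= 1):
            raise ValueError("censor_rate must be in [0, 1]")
        if self.clone_size_law not in ("lognormal", "power"):
            raise ValueError(f"unknown clone_size_law: {self.clone_size_law}")
        if self.clone_size_law == "power" and self.clone_size_alpha <= 1:
            raise ValueError("power-law exponent must exceed 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class GroundTruth:
    """Latent quantities of a simulated subject, for recovery tests."""

    clone_keys: pd.DataFrame  # columns CLONE_KEY_COLS (+ cdr3a_nt)
    latent_freqs: dict[int, np.ndarray]  # day -> frequency vector over clones
    expansion_rate: np.ndarray  # E_true, log2 per interval
    compositions: dict[int, np.ndarray]  # day -> (n_clones, 4) over STATE_FRACTIONS
    signature_genes: list[str] = field(default_factory=list)
    decoy_genes: list[str] = field(default_factory=list)
    gene_names: list[str] = field(default_factory=list)
    subject_scores: pd.Series | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "clone_keys": self.clone_keys.to_dict(orient="list"),
            "latent_freqs": {str(d): f.tolist() for d, f in self.latent_freqs.items()},
            "expansion_rate": self.expansion_rate.tolist(),
            "compositions": {str(d): c.tolist() for d, c in self.compositions.items()},
            "signature_genes": self.signature_genes,
            "decoy_genes": self.decoy_genes,
            "gene_names": self.gene_names,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            clone_keys=pd.DataFrame(payload["clone_keys"]),
            latent_freqs={int(d): np.array(f) for d, f in payload["latent_freqs"].items()},
            expansion_rate=np.array(payload["expansion_rate"]),
            compositions={int(d): np.array(c) for d, c in payload["compositions"].items()},
            signature_genes=payload["signature_genes"],
            decoy_genes=payload["decoy_genes"],
            gene_names=payload["gene_names"],
        )


_NT = np.array(list("ACGT"))


def _random_cdr3(rng: np.random.Generator, n: int, length_range=(30, 45)) -> list[str]:
    """Unique random CDR3 nucleotide strings (TGT...TTT framing, arbitrary core)."""
    out: set[str] = set()
    while len(out) < n:
        length = int(rng.integers(*length_range))
        core = "".join(rng.choice(_NT, size=length))
        out.add("TGT" + core + "TTT")
    return sorted(out)


def _make_clone_keys(rng: np.random.Generator, n: int) -> pd.DataFrame:
    cdr3b = _random_cdr3(rng, n)
    cdr3a = _random_cdr3(rng, n)
    df = pd.DataFrame(
        {
            "v_call": [f"TRBV{int(rng.integers(1, 31))}" for _ in range(n)],
            "d_call": [f"TRBD{int(rng.integers(1, 3))}" for _ in range(n)],
            "j_call": [f"TRBJ{int(rng.integers(1, 3))}-{int(rng.integers(1, 7))}" for _ in range(n)],
            "cdr3_nt": cdr3b,
            "cdr3a_nt": cdr3a,
        }
    )
    return df


def _clone_size_draw(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    if config.clone_size_law == "lognormal":
        if config.clone_size_sigma <= 0:
            raise ClonetrackError("degenerate size law: sigma must be positive")
        sizes = rng.lognormal(config.clone_size_mu, config.clone_size_sigma, config.n_clones)
    else:
        # Pareto with exponent alpha > 1 (heavy tail)
        sizes = (1.0 - rng.random(config.n_clones)) ** (-1.0 / (config.clone_size_alpha - 1.0))
    return sizes / sizes.sum()


def _overdispersed_probs(f: np.ndarray, rho: float, rng: np.random.Generator) -> np.ndarray:
    """Dirichlet perturbation of latent frequencies with concentration (1-rho)/rho."""
    if rho <= 0:
        return f
    conc = (1.0 - rho) / rho
    alpha = np.maximum(f * conc, 1e-12)
    p = rng.dirichlet(alpha)
    # guard against numerically zero simplex corners
    return p / p.sum()


def _baseline_compositions(config: SimConfig, e_true: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    comp = rng.dirichlet(np.asarray(config.composition_alpha, dtype=float), config.n_clones)
    # expanding clones start precursor-rich, contracting ones terminal-rich
    tilt = 2.0 ** (config.composition_E_coupling * e_true)
    comp[:, 1] *= tilt
    comp[:, 3] /= tilt
    return comp / comp.sum(axis=1, keepdims=True)


def _evolve_compositions(config: SimConfig, comp: np.ndarray, e_true: np.ndarray) -> np.ndarray:
    """Differentiation flux: pre->term for expanding clones, term->pre for contracting."""
    nxt = comp.copy()
    forward = np.clip(config.flux_per_log2 * np.maximum(e_true, 0.0), 0.0, 1.0)
    back = np.clip(config.regression_per_log2 * np.maximum(-e_true, 0.0), 0.0, 1.0)
    d_fwd = np.minimum(nxt[:, 1], forward)
    nxt[:, 1] -= d_fwd
    nxt[:, 3] += d_fwd
    d_back = np.minimum(nxt[:, 3], back)
    nxt[:, 3] -= d_back
    nxt[:, 1] += d_back
    return nxt


def _counts_to_sample(
    counts: np.ndarray,
    keys: pd.DataFrame,
    *,
    sample_id: str,
    subject_id: str,
    site: str,
    day: int,
    fraction: str = "unsorted",
    cells_sorted: int | None = None,
    cells_aliquoted_sc: int = 0,
) -> RepertoireSample | None:
    mask = counts > 0
    if not mask.any():
        return None
    df = keys.loc[mask, list(CLONE_KEY_COLS)].copy()
    df["read_count"] = counts[mask].astype(np.int64)
    total = int(counts.sum())
    return RepertoireSample(
        sample_id=sample_id,
        subject_id=subject_id,
        site=site,
        day=day,
        fraction=fraction,
        clonotypes=df.reset_index(drop=True),
        cells_sorted=total if cells_sorted is None else cells_sorted,
        cells_aliquoted_sc=cells_aliquoted_sc,
    )


def gen_repertoire(
    config: SimConfig,
    rng: np.random.Generator | None = None,
    subject_id: str = "mouse1",
) -> tuple[list[RepertoireSample], GroundTruth]:
    """Simulate bilateral (left/right) unsorted repertoires at each timepoint.

    Samples at the same timepoint share the latent frequency vector; later
    latents equal earlier latents times 2^E_true, renormalized (within-tumor
    competition).  Each sample is a multinomial draw of
    ``n_reads_per_sample`` reads, optionally beta-binomially overdispersed
    via a Dirichlet perturbation with parameter ``bilateral_noise_rho``.
    """
    rng = config.rng() if rng is None else rng
    keys = _make_clone_keys(rng, config.n_clones)
    f0 = _clone_size_draw(config, rng)
    e_true = rng.normal(config.expansion_mu, config.expansion_sigma, config.n_clones)

    latents: dict[int, np.ndarray] = {}
    comps: dict[int, np.ndarray] = {}
    f = f0
    comp = _baseline_compositions(config, e_true, rng)
    for i, day in enumerate(config.days):
        if i > 0:
            f = f * 2.0**e_true
            f = f / f.sum()
            comp = _evolve_compositions(config, comp, e_true)
        latents[day] = f
        comps[day] = comp

    samples: list[RepertoireSample] = []
    for day in config.days:
        for site in ("left", "right"):
            p = _overdispersed_probs(latents[day], config.bilateral_noise_rho, rng)
            counts = rng.multinomial(config.n_reads_per_sample, p)
            s = _counts_to_sample(
                counts,
                keys,
                sample_id=f"{subject_id}_d{day}_{site}",
                subject_id=subject_id,
                site=site,
                day=day,
            )
            if s is not None:
                samples.append(s)

    truth = GroundTruth(
        clone_keys=keys,
        latent_freqs=latents,
        expansion_rate=e_true,
        compositions=comps,
    )
    return samples, truth


def gen_sorted_fractions(
    sample: RepertoireSample,
    compositions: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> list[RepertoireSample]:
    """Partition an unsorted sample into the four sorted-fraction datasets.

    ``compositions`` is indexed by CDR3 nucleotide sequence with columns
    ``PD1neg, precursor, intermediate, terminal`` summing to 1 per row.
    Clone reads are split multinomially by composition; per-fraction
    metadata records the cells sorted and the cells aliquoted for
    single-cell sequencing.  Fraction counts sum to the unsorted counts
    exactly.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    rows = compositions.loc[sample.clonotypes["cdr3_nt"]].to_numpy(dtype=float)
    sums = rows.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-6):
        raise ClonetrackError("composition rows must sum to 1")
    rows = rows / sums[:, None]
    counts = sample.clonotypes["read_count"].to_numpy()
    split = np.vstack([rng.multinomial(int(c), p) for c, p in zip(counts, rows)])

    out: list[RepertoireSample] = []
    for j, frac in enumerate(STATE_FRACTIONS):
        frac_counts = split[:, j]
        total = int(frac_counts.sum())
        aliquot = int(round(config.aliquot_fraction * total))
        s = _counts_to_sample(
            frac_counts,
            sample.clonotypes,
            sample_id=f"{sample.sample_id}_{frac}",
            subject_id=sample.subject_id,
            site=sample.site,
            day=sample.day,
            fraction=frac,
            cells_sorted=total,
            cells_aliquoted_sc=aliquot,
        )
        if s is not None:
            out.append(s)
    return out


def _gene_names(config: SimConfig, rng: np.random.Generator) -> tuple[list[str], list[str], list[str]]:
    sig = [f"Eg{i:03d}" for i in range(config.n_signature_genes)]
    decoy_prefixes = ["mt-Sg", "Rps9x", "Rpl9x", "Mrpl8x"]
    decoys = [
        f"{decoy_prefixes[i % len(decoy_prefixes)]}{i}" for i in range(config.n_decoy_excluded_genes)
    ]
    background = [f"Bg{i:04d}" for i in range(config.n_background_genes)]
    return sig, decoys, background


def gen_expression(
    truth: GroundTruth,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    subject_id: str = "mouse1",
) -> tuple[ad.AnnData, pd.DataFrame]:
    """Simulate single-cell expression + TCR annotations for each clone.

    Cells are assigned to PD-1+ states in proportion to the clone's latent
    composition, with precursor cells enriched by the sorting factor.
    Counts are Poisson(library_size x gene_rate); planted signature genes in
    precursor cells have their rate multiplied by
    ``2^(signature_effect x E_true)``, and by a damped version of that shift
    in the other exhausted states.  Returns the count matrix (cells x genes)
    and a cell annotation table with clone CDR3s, state, and day.
    """
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    sig, decoys, background = _gene_names(config, rng)
    genes = sig + decoys + background
    n_genes = len(genes)
    planted = np.zeros(n_genes, dtype=bool)
    planted[: len(sig) + len(decoys)] = True

    base_rate = rng.lognormal(0.0, 1.0, n_genes)
    base_rate /= base_rate.sum()

    n_clones = len(truth.clone_keys)
    blocks: list[np.ndarray] = []
    meta: list[dict] = []
    cell_counter = 0
    any_precursor = False
    for day in sorted(truth.latent_freqs):
        comp = truth.compositions[day]
        # cells sampled from PD-1+ states only, precursor-enriched by sorting
        weights = comp[:, 1:4].copy()
        weights[:, 0] *= config.precursor_enrichment
        weights = weights / np.maximum(weights.sum(axis=1, keepdims=True), 1e-12)
        for ci in range(n_clones):
            n_cells = config.cells_per_clone
            states = rng.choice(
                ["precursor", "intermediate", "terminal"], size=n_cells, p=weights[ci]
            )
            # a slice of highly proliferative cells, mostly terminal-derived
            prolif = (states == "terminal") & (rng.random(n_cells) < 0.15)
            states = states.astype(object)
            states[prolif] = "proliferating"
            if (states == "precursor").any():
                any_precursor = True
            libs = rng.lognormal(np.log(config.library_size_mean), config.library_size_sigma, n_cells)
            e = truth.expansion_rate[ci]
            shift_full = 2.0 ** (config.signature_effect * e)
            shift_other = 2.0 ** (config.signature_effect * config.signature_effect_other_states * e)
            rates = np.tile(base_rate, (n_cells, 1))
            is_pre = states == "precursor"
            rates[np.ix_(is_pre, planted)] *= shift_full
            rates[np.ix_(~is_pre, planted)] *= shift_other
            rates /= rates.sum(axis=1, keepdims=True)
            lam = libs[:, None] * rates
            blocks.append(rng.poisson(lam).astype(np.int32))
            for s in states:
                meta.append(
                    {
                        "cell_id": f"{subject_id}_c{cell_counter:06d}",
                        "cdr3b_nt": truth.clone_keys.loc[ci, "cdr3_nt"],
                        "cdr3a_nt": truth.clone_keys.loc[ci, "cdr3a_nt"],
                        "state": s,
                        "day": day,
                        "subject_id": subject_id,
                    }
                )
                cell_counter += 1
    if not any_precursor:
        raise ClonetrackError("no precursor cells generated")

    x = sp.csr_matrix(np.vstack(blocks))
    cells = pd.DataFrame(meta)
    adata = ad.AnnData(X=x, obs=cells.set_index("cell_id", drop=False))
    adata.var_names = genes
    truth.signature_genes = sig
    truth.decoy_genes = decoys
    truth.gene_names = genes
    return adata, cells


def gen_survival(
    subject_scores: pd.Series,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Exponential survival with hazard h0 * exp(hazard_beta * score).

    With probability ``censor_rate`` a subject is independently censored at
    a uniform fraction of its event time.
    """
    rng = np.random.default_rng(config.seed + 3) if rng is None else rng
    scores = np.asarray(subject_scores, dtype=float)
    if not np.isfinite(scores).all():
        raise ClonetrackError("non-finite subject scores")
    hazard = config.baseline_hazard * np.exp(config.hazard_beta * scores)
    times = rng.exponential(1.0 / hazard)
    censored = rng.random(len(scores)) < config.censor_rate
    u = rng.random(len(scores))
    obs_times = np.where(censored, times * u, times)
    obs_times = np.maximum(obs_times, 1e-9)
    return pd.DataFrame(
        {
            "subject_id": list(subject_scores.index),
            "time": obs_times,
            "event": (~censored).astype(int),
            "score": scores,
        }
    )


def make_ortholog_table(gene_names: list[str]) -> pd.DataFrame:
    """Synthetic human<->mouse symbol table (human = uppercased mouse name)."""
    human = [g.upper() for g in gene_names]
    return pd.DataFrame({"human": human, "mouse": gene_names})


@dataclass
class HumanCohort:
    """Synthetic longitudinal single-cell cohort in human-dataset form."""

    adata: ad.AnnData  # pre-therapy cells x human genes
    cells: pd.DataFrame  # cell_id, clone_id, subject_id, timepoint, cluster
    clone_counts: pd.DataFrame  # clone_id, subject_id, cells_pre, cells_post
    expansion_rate: pd.Series  # true E per clone
    subject_scores: pd.Series  # latent subject-level score
    response: pd.Series  # subject -> responder / non-responder


def gen_human_cohort(
    config: SimConfig,
    rng: np.random.Generator | None = None,
    n_subjects: int = 8,
    clones_per_subject: int = 25,
    mean_cells_pre: float = 8.0,
) -> HumanCohort:
    """Simulate a pre/post-therapy single-cell RNA/TCR cohort.

    Clone cell counts post-therapy scale the pre-therapy counts by
    ``2^E``; pre-therapy cells carry planted-gene expression coupled to E
    exactly as in the mouse generator, but under human gene symbols.
    Subject scores are the mean latent E of the subject's clones; responders
    are subjects with above-median latent score.
    """
    rng = np.random.default_rng(config.seed + 4) if rng is None else rng
    sig, decoys, background = _gene_names(config, rng)
    mouse_genes = sig + decoys + background
    genes = [g.upper() for g in mouse_genes]
    n_genes = len(genes)
    planted = np.zeros(n_genes, dtype=bool)
    planted[: len(sig) + len(decoys)] = True
    base_rate = rng.lognormal(0.0, 1.0, n_genes)
    base_rate /= base_rate.sum()

    clone_rows = []
    cell_rows = []
    blocks = []
    subj_scores = {}
    cell_counter = 0
    for si in range(n_subjects):
        subject = f"pt{si + 1:02d}"
        e = rng.normal(config.expansion_mu, config.expansion_sigma, clones_per_subject)
        subj_scores[subject] = float(np.mean(e))
        sizes = rng.lognormal(np.log(mean_cells_pre), 0.6, clones_per_subject)
        cells_pre = rng.poisson(sizes)
        cells_post = rng.poisson(sizes * 2.0**e)
        for ci in range(clones_per_subject):
            clone_id = f"{subject}_cl{ci:03d}"
            clone_rows.append(
                {
                    "clone_id": clone_id,
                    "subject_id": subject,
                    "cells_pre": int(cells_pre[ci]),
                    "cells_post": int(cells_post[ci]),
                    "E_true": float(e[ci]),
                }
            )
            n_cells = int(cells_pre[ci])
            if n_cells == 0:
                continue
            libs = rng.lognormal(np.log(config.library_size_mean), config.library_size_sigma, n_cells)
            rates = np.tile(base_rate, (n_cells, 1))
            rates[:, planted] *= 2.0 ** (config.signature_effect * e[ci])
            rates /= rates.sum(axis=1, keepdims=True)
            blocks.append(rng.poisson(libs[:, None] * rates).astype(np.int32))
            exhausted = rng.random(n_cells) < 0.7
            for j in range(n_cells):
                cell_rows.append(
                    {
                        "cell_id": f"{subject}_c{cell_counter:06d}",
                        "clone_id": clone_id,
                        "subject_id": subject,
                        "timepoint": "pre",
                        "cluster": "CD8_ex" if exhausted[j] else "CD8_other",
                    }
                )
                cell_counter += 1

    cells = pd.DataFrame(cell_rows)
    adata = ad.AnnData(X=sp.csr_matrix(np.vstack(blocks)), obs=cells.set_index("cell_id", drop=False))
    adata.var_names = genes
    clone_counts = pd.DataFrame(clone_rows)
    scores = pd.Series(subj_scores, name="score")
    response = pd.Series(
        np.where(scores > scores.median(), "responder", "non-responder"),
        index=scores.index,
        name="response",
    )
    return HumanCohort(
        adata=adata,
        cells=cells,
        clone_counts=clone_counts.set_index("clone_id"),
        expansion_rate=clone_counts.set_index("clone_id")["E_true"],
        subject_scores=scores,
        response=response,
    )
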