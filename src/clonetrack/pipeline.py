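"""End-to-end orchestration: mouse (bulk + single-cell) and human (single-cell)
pipelines over a synthetic or file-based cohort, with a reproducible manifest.

The mouse pipeline mirrors the study design: a same-day bilateral tumor
pair trains the dispersion model, the day-14 and day-21 tumors are sorted
into four exhaustion fractions and bulk TCR-sequenced, clones are merged
and tested for expansion, the tumor-reactive filter applies, precursor
cells from expanding vs contracting clones drive the signature derivation,
and clone-level scores are regressed against measured expansion.

The human pipeline takes a signature (typically the mouse-derived one,
ortholog-translated), classifies clone dynamics with the >1.5-fold
cell-count rule, compares scores of top expanding vs contracting clones,
and optionally stratifies survival by median score.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clones as cl
from . import dynamics as dyn
from . import signature as sig
from . import simulate as sim
from . import stats as st
from .io import ClonetrackError, OrthologMap, PipelineConfig

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass
class RunManifest:
    """Auditable record of one pipeline run."""

    config_hash: str
    seed: int
    stage_counts: dict[str, int] = field(default_factory=dict)
    results: dict[str, float] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    version: str = __version__

    def record(self, stage: str, count: int) -> None:
        self.stage_counts[stage] = int(count)
        logger.info("stage %s: %d", stage, count)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))


def _hash_config(config: PipelineConfig, sim_config: sim.SimConfig | None) -> str:
    payload = {"pipeline": config.to_dict()}
    if sim_config is not None:
        payload["sim"] = dataclasses.asdict(sim_config)
    blob = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _file_digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


@dataclass
class MousePipelineResult:
    manifest: RunManifest
    cloneset: cl.CloneSet
    calls: pd.DataFrame
    signature: sig.GeneSignature
    stringent: sig.GeneSignature
    clone_scores: pd.DataFrame  # per clone: precursor mean, weighted score, E
    regression_precursor: st.RegressionResult | None
    regression_weighted: st.RegressionResult | None
    truth: sim.GroundTruth | None = None


def run_mouse_pipeline(
    config: PipelineConfig,
    sim_config: sim.SimConfig | None = None,
    out_dir: str | Path | None = None,
) -> MousePipelineResult:
    """Run the mouse-mode analysis on a simulated subject.

    Stages (any failure aborts naming the stage): simulate -> build_clones
    -> fit_dispersion -> dynamics calls -> tumor-reactive filter ->
    attach cells -> precursor panel -> DEG -> signature -> scoring ->
    regression.  Writes tables and the manifest to ``out_dir`` when given.
    """
    sim_config = sim_config or sim.SimConfig(seed=config.seed)
    manifest = RunManifest(config_hash=_hash_config(config, sim_config), seed=config.seed)
    out = Path(out_dir) if out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    stage = "simulate"
    try:
        rng = sim_config.rng()
        samples, truth = sim.gen_repertoire(sim_config, rng)
        comp_by_cdr3 = {
            day: pd.DataFrame(
                truth.compositions[day],
                index=truth.clone_keys["cdr3_nt"],
                columns=list(sim.STATE_FRACTIONS),
            )
            for day in sim_config.days
        }
        # analysis tumors: first site on the first day, second on the second
        day1, day2 = sim_config.days[0], sim_config.days[-1]
        unsorted = {(s.day, s.site): s for s in samples}
        analysis_samples = []
        for day, site in ((day1, "left"), (day2, "right")):
            analysis_samples.extend(
                sim.gen_sorted_fractions(unsorted[(day, site)], comp_by_cdr3[day], sim_config, rng)
            )
        adata, cells = sim.gen_expression(truth, sim_config, rng)

        stage = "build_clones"
        cloneset = cl.build_clones(analysis_samples)
        manifest.record("clones_total", cloneset.n_clones)

        stage = "fit_dispersion"
        pairs = []
        for day in sim_config.days:
            left, right = unsorted[(day, "left")], unsorted[(day, "right")]
            merged = cl.build_clones([left, right])
            x1 = merged.counts[merged.counts["site"] == "left"].set_index(
                "cdr3_nt")["count"]
            x2 = merged.counts[merged.counts["site"] == "right"].set_index(
                "cdr3_nt")["count"]
            union = x1.index.union(x2.index)
            pairs.append(
                (
                    x1.reindex(union, fill_value=0).to_numpy(),
                    left.total_reads,
                    x2.reindex(union, fill_value=0).to_numpy(),
                    right.total_reads,
                )
            )
        model = dyn.fit_dispersion(pairs)

        stage = "dynamics"
        calls = dyn.classify_dynamics(
            dyn.dynamics_calls(cloneset, day1, day2, model), alpha=config.fdr_alpha
        )
        manifest.record("clones_testable", int(calls["p_value"].notna().sum()))
        manifest.record("clones_expanding", int((calls["call"] == "expanding").sum()))
        manifest.record("clones_contracting", int((calls["call"] == "contracting").sum()))

        stage = "tumor_reactive_filter"
        reactive = cl.tumor_reactive_filter(cloneset)
        manifest.record("clones_tumor_reactive", reactive.n_clones)

        stage = "attach_cells"
        reactive = cl.attach_cells(reactive, cells)
        manifest.record("cells_total", len(cells))
        manifest.record(
            "cells_linked", int((reactive.cells["link_status"] == "linked").sum())
        )

        stage = "precursor_panel"
        panel = cl.restrict_precursor_panel(reactive, days=(day1, day2))
        manifest.record("clones_sc_panel", panel.n_clones)

        stage = "deg"
        norm = sig.normalize_log(adata)
        panel_keys = set(panel.keys)
        calls_by_key = calls["call"]
        cell_tbl = panel.cells
        linked = cell_tbl[cell_tbl["link_status"] == "linked"].copy()
        linked["call"] = [
            calls_by_key.get(k, "untestable") for k in linked["clone_key"]
        ]
        pre14 = linked[(linked["state"] == "precursor") & (linked["day"] == day1)]
        grp_exp = pre14[pre14["call"] == "expanding"]["cell_id"]
        grp_con = pre14[pre14["call"] == "contracting"]["cell_id"]
        manifest.record("deg_cells_expanding", len(grp_exp))
        manifest.record("deg_cells_contracting", len(grp_con))
        deg = sig.rank_sum_deg(norm, grp_exp.tolist(), grp_con.tolist())

        stage = "signature"
        signature = sig.build_signature(deg, alpha=config.deg_alpha)
        stringent = sig.build_signature(
            deg, alpha=config.stringent_alpha, name="expansion_stringent"
        )
        manifest.record("signature_size", len(signature))
        manifest.record("stringent_signature_size", len(stringent))

        stage = "scoring"
        scored = sig.score_units(
            norm, signature, n_bins=config.n_bins, ctrl_size=config.ctrl_size,
            seed=config.seed,
        )
        freqs1 = cl.clone_frequency(panel, day1)
        freqs2 = cl.clone_frequency(panel, day2)
        comps1 = cl.phenotype_compositions(panel, day1)
        state_means = sig.clone_state_mean_scores(scored.scores, panel.cells, day=day1)
        rows = []
        for key in panel.keys:
            f1, f2 = float(freqs1.loc[key]), float(freqs2.loc[key])
            e_obs = np.log2(f2 / f1) if f1 > 0 and f2 > 0 else np.nan
            pre_mean = sig.clone_mean_score(
                scored.scores, panel.cells, key, day=day1,
                min_cells=config.min_precursor_cells,
            )
            weighted = np.nan
            if key in comps1.index and key in state_means.index:
                try:
                    weighted = sig.weighted_clone_score(
                        state_means.loc[[key]].iloc[0], comps1.loc[key]
                    )
                except ClonetrackError:
                    weighted = np.nan
            rows.append(
                {"clone_key": key, "f_day1": f1, "f_day2": f2, "E": e_obs,
                 "precursor_score": pre_mean, "weighted_score": weighted}
            )
        clone_scores = pd.DataFrame(rows).set_index("clone_key")
        manifest.record(
            "clones_scored",
            int(clone_scores[["precursor_score", "E"]].notna().all(axis=1).sum()),
        )

        stage = "regression"
        reg_pre = reg_wt = None
        ok_pre = clone_scores[["precursor_score", "E"]].dropna()
        if len(ok_pre) >= 3:
            reg_pre = st.regress(
                ok_pre["precursor_score"], ok_pre["E"], seed=config.seed
            )
            manifest.results["precursor_score_E_r"] = reg_pre.r
            manifest.results["precursor_score_E_p"] = reg_pre.p_value
        ok_wt = clone_scores[["weighted_score", "E"]].dropna()
        if len(ok_wt) >= 3:
            reg_wt = st.regress(ok_wt["weighted_score"], ok_wt["E"], seed=config.seed)
            manifest.results["weighted_score_E_r"] = reg_wt.r
            manifest.results["weighted_score_E_p"] = reg_wt.p_value
    except ClonetrackError as err:
        raise ClonetrackError(f"mouse pipeline failed at stage {stage}: {err}") from err

    if out:
        cl.export_clone_table(cloneset, out / "clone_table.tsv")
        calls.to_csv(out / "dynamics_calls.tsv", sep="\t")
        signature.to_tsv(out / "expansion_signature.tsv")
        stringent.to_tsv(out / "expansion_signature_stringent.tsv")
        clone_scores.to_csv(out / "clone_scores.csv")
        for p in sorted(out.glob("*")):
            if p.is_file() and p.name != "manifest.json":
                manifest.outputs[p.name] = _file_digest(p)
        manifest.to_json(out / "manifest.json")

    return MousePipelineResult(
        manifest=manifest, cloneset=cloneset, calls=calls, signature=signature,
        stringent=stringent, clone_scores=clone_scores,
        regression_precursor=reg_pre, regression_weighted=reg_wt, truth=truth,
    )


@dataclass
class HumanPipelineResult:
    manifest: RunManifest
    clone_table: pd.DataFrame  # per clone: cells pre/post, call, mean score
    comparison: st.EnrichmentComparison | None
    survival: dict | None


def run_human_pipeline(
    config: PipelineConfig,
    signature: sig.GeneSignature,
    sim_config: sim.SimConfig | None = None,
    ortholog_map: OrthologMap | None = None,
    out_dir: str | Path | None = None,
    with_survival: bool = True,
) -> HumanPipelineResult:
    """Run the human-mode analysis on a simulated pre/post-therapy cohort.

    Clones restricted to those with at least one exhausted-cluster cell;
    dynamics from the >fold_threshold cell-count rule on clones detected at
    both timepoints; the (mouse) signature is ortholog-translated before
    scoring; the top-N expanding and contracting clones' mean pre-therapy
    scores are compared by Kruskal-Wallis; subject-level mean scores
    median-split the cohort for survival.
    """
    sim_config = sim_config or sim.SimConfig(seed=config.seed)
    manifest = RunManifest(config_hash=_hash_config(config, sim_config), seed=config.seed)
    out = Path(out_dir) if out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    stage = "simulate"
    try:
        cohort = sim.gen_human_cohort(sim_config)
        manifest.record("clones_total", len(cohort.clone_counts))

        stage = "ortholog_translation"
        if signature.species == "mouse":
            if ortholog_map is None:
                # synthetic cohort uses uppercased mouse symbols as human genes
                table = sim.make_ortholog_table(list(signature.genes))
                ortholog_map = OrthologMap(
                    human_to_mouse=dict(zip(table["human"], table["mouse"])),
                    mouse_to_human=dict(zip(table["mouse"], table["human"])),
                )
            genes = ortholog_map.translate(signature.genes, to="human")
            if not genes:
                raise ClonetrackError("missing ortholog map when species=human")
            hsig = sig.GeneSignature(
                name=signature.name, genes=genes, species="human",
                derivation={**signature.derivation, "translated_from": "mouse"},
            )
        else:
            hsig = signature
        manifest.record("signature_translated_size", len(hsig))

        stage = "exhausted_clone_filter"
        ex_cells = cohort.cells[cohort.cells["cluster"].str.contains("ex", case=False)]
        ex_clones = set(ex_cells["clone_id"])
        table = cohort.clone_counts[cohort.clone_counts.index.isin(ex_clones)].copy()
        manifest.record("clones_exhausted", len(table))

        stage = "fold_change_classify"
        both = table[(table["cells_pre"] > 0) & (table["cells_post"] > 0)]
        if len(both) == 0:
            raise ClonetrackError("no clones detected at both timepoints")
        table = table.copy()
        table["call"] = [
            dyn.fold_change_classify(r.cells_pre, r.cells_post, config.fold_threshold)
            if (r.cells_pre > 0 or r.cells_post > 0)
            else "untestable"
            for r in table.itertuples()
        ]
        manifest.record("clones_codetected", len(both))

        stage = "scoring"
        norm = sig.normalize_log(cohort.adata)
        scored = sig.score_units(
            norm, hsig, n_bins=config.n_bins, ctrl_size=config.ctrl_size,
            seed=config.seed,
        )
        per_cell = scored.scores
        cell_clone = cohort.cells.set_index("cell_id")["clone_id"]
        clone_mean = per_cell.groupby(cell_clone.reindex(per_cell.index)).mean()
        table["mean_score"] = clone_mean.reindex(table.index)

        stage = "top_clones"
        scored_both = table.loc[both.index].dropna(subset=["mean_score"])
        comparison = None
        top_n = config.top_n_clones
        groups = {}
        for label in ("expanding", "contracting"):
            grp = scored_both[scored_both["call"] == label]
            grp = grp.assign(size=grp["cells_pre"] + grp["cells_post"])
            grp = grp.sort_values(["size"], ascending=False, kind="mergesort")
            if len(grp) < top_n:
                logger.warning(
                    "top-%d requested but only %d %s clones; using all", top_n, len(grp), label
                )
            groups[label] = grp.head(top_n)["mean_score"].to_numpy()
        manifest.record("top_expanding", len(groups["expanding"]))
        manifest.record("top_contracting", len(groups["contracting"]))
        if all(len(v) for v in groups.values()):
            comparison = st.compare_groups(groups)
            manifest.results["top_clone_kw_p"] = comparison.p_value

        stage = "survival"
        survival = None
        if with_survival:
            subj_measured = per_cell.groupby(
                cohort.cells.set_index("cell_id")["subject_id"].reindex(per_cell.index)
            ).mean()
            surv_table = sim.gen_survival(cohort.subject_scores, sim_config)
            survival = st.survival_by_split(surv_table, subj_measured)
            manifest.results["logrank_p"] = survival["p_value"]
    except ClonetrackError as err:
        raise ClonetrackError(f"human pipeline failed at stage {stage}: {err}") from err

    if out:
        table.to_csv(out / "human_clone_table.csv")
        for p in sorted(out.glob("*")):
            if p.is_file() and p.name != "manifest.json":
                manifest.outputs[p.name] = _file_digest(p)
        manifest.to_json(out / "manifest.json")

    return HumanPipelineResult(
        manifest=manifest, clone_table=table, comparison=comparison, survival=survival
    )
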