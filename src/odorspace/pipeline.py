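"""End-to-end analysis orchestration.

One YAML config drives the whole workflow: simulate (or load) an odorant
table, embed fingerprints into 3D, cluster at the configured levels,
profile odor notes per cluster, compute co-occurrence matrices, select
odor-profile subsets around the planted mixture components, and run the
pharmacophore stages.  Every stage output is written under the run
directory and recorded in a manifest (parameters, derived seeds, paths,
checksums), so a rerun from the same config reproduces identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from odorspace import dataset as dcore
from odorspace import embed as emb
from odorspace import selection as sel
from odorspace import stats as st
from odorspace import synthetic as syn
from odorspace.pharmacophore import (
    AlignmentFailure,
    align_hypotheses,
    find_common_pharmacophores,
    generate_conformers,
    interfeature_distances,
)

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "out_dir": "results/run",
    "dataset": {"source": "synthetic", "scale": 1.0, "plant_mixture": True},
    "embedding": {"n_neighbors": 15, "min_dist": 0.1, "metric": "jaccard"},
    "clustering": {"methods": ["kmeans", "som"], "levels": [4, 9, 16],
                   "k_range": [2, 10]},
    "profiles": {"top_k_notes": 25},
    "selection": {"cap": 10},
    "pharmacophore": {"enabled": True, "single_molecules": ["WL", "IA", "V", "F"],
                      "joint": [["WL", "IA"]], "max_features": 6},
}


@dataclass
class RunManifest:
    config: dict
    seeds: dict[str, int] = field(default_factory=dict)
    outputs: dict[str, dict] = field(default_factory=dict)
    timings: dict[str, float] = field(default_factory=dict)

    def record(self, name: str, path: Path) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.outputs[name] = {"path": str(path), "sha256": digest}

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(
            {"config": self.config, "seeds": self.seeds,
             "outputs": self.outputs, "timings": self.timings}, indent=2))


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed (< 2^31)."""
    return int(np.random.SeedSequence(
        [int(global_seed), zlib.crc32(stage.encode())]).generate_state(1)[0] % (2 ** 31))


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def _validate(config: dict) -> list[str]:
    errors = []
    known = set(DEFAULT_CONFIG)
    errors += [f"unknown config section: {k}" for k in config if k not in known]
    ds = config.get("dataset", {})
    if ds.get("source") != "synthetic" and not Path(str(ds.get("source", ""))).exists():
        errors.append(f"dataset.source must be 'synthetic' or an existing CSV path, "
                      f"got {ds.get('source')!r}")
    for m in config.get("clustering", {}).get("methods", []):
        if m not in ("kmeans", "som"):
            errors.append(f"unknown clustering method {m!r}")
    for lvl in config.get("clustering", {}).get("levels", []):
        if int(lvl) < 1:
            errors.append(f"cluster level must be >= 1, got {lvl}")
    return errors


def _som_grid(level: int) -> tuple[int, int]:
    rows = int(np.floor(np.sqrt(level)))
    while level % rows:
        rows -= 1
    return rows, level // rows


def run_pipeline(config_path_or_dict: str | Path | dict, out_dir: str | Path | None = None) -> RunManifest:
    """Run the full analysis from a config; returns the saved manifest."""
    if isinstance(config_path_or_dict, (str, Path)):
        user_cfg = yaml.safe_load(Path(config_path_or_dict).read_text()) or {}
    else:
        user_cfg = dict(config_path_or_dict)
    cfg = _merge(DEFAULT_CONFIG, user_cfg)
    problems = _validate(cfg)
    if problems:
        raise ValueError("invalid pipeline config:\n  " + "\n  ".join(problems))

    out = Path(out_dir if out_dir is not None else cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=cfg)
    seed = int(cfg["seed"])

    def timed(stage):
        t0 = time.time()

        def done():
            manifest.timings[stage] = round(time.time() - t0, 2)
        return done

    # --- dataset -----------------------------------------------------------
    tick = timed("dataset")
    manifest.seeds["dataset"] = stage_seed(seed, "dataset")
    if cfg["dataset"]["source"] == "synthetic":
        gen_cfg = syn.default_config(seed=manifest.seeds["dataset"],
                                     scale=float(cfg["dataset"].get("scale", 1.0)))
        ds, truth = syn.generate_dataset(gen_cfg)
        if cfg["dataset"].get("plant_mixture", True):
            ds = syn.plant_mixture_components(ds)
        truth_path = out / "families.csv"
        with truth_path.open("w") as fh:
            fh.write("id,family\n")
            for rid, fam in sorted(truth.items()):
                fh.write(f"{rid},{fam}\n")
        manifest.record("families", truth_path)
    else:
        ds = dcore.read_odorant_table(cfg["dataset"]["source"])
    ds_path = out / "dataset.csv"
    dcore.write_odorant_table(ds, ds_path)
    manifest.record("dataset", ds_path)
    logger.info("dataset: %d records, %d vocabulary notes", len(ds), len(ds.vocabulary))
    tick()

    # --- embedding ---------------------------------------------------------
    tick = timed("embedding")
    manifest.seeds["embedding"] = stage_seed(seed, "embedding")
    fps = emb.compute_fingerprints(ds)
    e3 = emb.embed_umap(fps, seed=manifest.seeds["embedding"], **{
        k: cfg["embedding"][k] for k in ("n_neighbors", "min_dist", "metric")})
    emb_path = out / "embedding.csv"
    with emb_path.open("w") as fh:
        fh.write("id,x,y,z\n")
        for rid, row in zip(e3.ids, e3.coords):
            fh.write(f"{rid},{row[0]:.6f},{row[1]:.6f},{row[2]:.6f}\n")
    manifest.record("embedding", emb_path)
    tick()

    # --- clustering --------------------------------------------------------
    tick = timed("clustering")
    manifest.seeds["clustering"] = stage_seed(seed, "clustering")
    k_lo, k_hi = cfg["clustering"]["k_range"]
    report = emb.select_cluster_count(e3, range(int(k_lo), int(k_hi) + 1),
                                      seed=manifest.seeds["clustering"])
    rep_path = out / "cluster_selection.csv"
    with rep_path.open("w") as fh:
        fh.write("k,wss,kelley_penalty\n")
        for k in report.k_range:
            pen = report.kelley_penalty.get(k, float("nan"))
            fh.write(f"{k},{report.wss[k]:.4f},{pen:.4f}\n")
    manifest.record("cluster_selection", rep_path)
    logger.info("optimal cluster count (Kelley penalty): %d", report.k_optimal)

    assignments: dict[str, emb.ClusterAssignment] = {}
    for method in cfg["clustering"]["methods"]:
        for level in cfg["clustering"]["levels"]:
            level = int(level)
            if method == "kmeans":
                asg = emb.cluster_kmeans(e3, level, seed=manifest.seeds["clustering"])
            else:
                rows, cols = _som_grid(level)
                asg = emb.cluster_som(e3, rows, cols, seed=manifest.seeds["clustering"])
            name = f"{method}{level}"
            assignments[name] = asg
            p = out / f"assignment_{name}.csv"
            with p.open("w") as fh:
                fh.write("id,method,level,cluster\n")
                for rid in e3.ids:
                    fh.write(f"{rid},{method},{level},{asg.labels[rid]}\n")
            manifest.record(f"assignment_{name}", p)
    tick()

    # --- odor-note statistics ---------------------------------------------
    tick = timed("profiles")
    top_level = max(int(l) for l in cfg["clustering"]["levels"])
    focus_name = f"som{top_level}" if f"som{top_level}" in assignments else next(iter(assignments))
    focus = assignments[focus_name]
    top_notes = st.top_frequent_notes(ds, min(int(cfg["profiles"]["top_k_notes"]),
                                              len(ds.vocabulary)))
    profiles = st.note_profiles(ds, focus, top_notes)
    prof_path = out / f"profiles_{focus_name}.csv"
    st.export_profile_tables(profiles, prof_path)
    manifest.record("profiles", prof_path)
    cooc = st.cooccurrence(ds, top_notes)
    cooc_path = out / "cooccurrence.csv"
    st.export_heatmap_tables(cooc, cooc_path)
    manifest.record("cooccurrence", cooc_path)
    manifest.record("cooccurrence_counts", cooc_path.with_name("cooccurrence_counts.csv"))
    tick()

    # --- subset selection --------------------------------------------------
    tick = timed("selection")
    sel_rows = []
    for ref_id in cfg["pharmacophore"]["single_molecules"]:
        if ref_id not in ds or ref_id not in focus.labels:
            continue
        cluster = focus.labels[ref_id]
        members = [ds.get(i) for i in focus.members(cluster) if i in ds]
        result = sel.select_subset(members, ds.get(ref_id),
                                   cap=int(cfg["selection"]["cap"]),
                                   vocabulary=ds.vocabulary, cluster=cluster)
        for sim, verdict in result.audit:
            sel_rows.append((ref_id, cluster, sim.candidate_id, sim.n_common,
                             sim.n_noncommon, round(sim.pct_common, 1),
                             round(sim.pct_noncommon, 1), verdict))
    sel_path = out / "subset_selection.csv"
    with sel_path.open("w") as fh:
        fh.write("reference,cluster,candidate,n_common,n_noncommon,"
                 "pct_common,pct_noncommon,verdict\n")
        for row in sel_rows:
            fh.write(",".join(str(x) for x in row) + "\n")
    manifest.record("subset_selection", sel_path)
    tick()

    # --- pharmacophores ----------------------------------------------------
    if cfg["pharmacophore"]["enabled"]:
        tick = timed("pharmacophore")
        manifest.seeds["pharmacophore"] = stage_seed(seed, "pharmacophore")
        hypotheses = {}
        for mid in cfg["pharmacophore"]["single_molecules"]:
            if mid not in ds:
                continue
            ens = generate_conformers(ds.get(mid).smiles, mid,
                                      seed=manifest.seeds["pharmacophore"])
            hyps = find_common_pharmacophores(
                [ens], max_features=int(cfg["pharmacophore"]["max_features"]))
            if hyps:
                hypotheses[mid] = hyps[0]
                p = out / f"hypothesis_{mid}.json"
                hyps[0].to_json(p)
                manifest.record(f"hypothesis_{mid}", p)
        dist_path = out / "interfeature_distances.csv"
        with dist_path.open("w") as fh:
            fh.write("hypothesis,feature_a,feature_b,distance_A\n")
            for mid, hyp in sorted(hypotheses.items()):
                for a, b, d in interfeature_distances(hyp):
                    fh.write(f"hyp-{mid}-c,{a},{b},{d:.3f}\n")
        manifest.record("interfeature_distances", dist_path)

        for pair in cfg["pharmacophore"].get("joint", []):
            if not all(m in ds for m in pair):
                continue
            ens = [generate_conformers(ds.get(m).smiles, m,
                                       seed=manifest.seeds["pharmacophore"])
                   for m in pair]
            joint = find_common_pharmacophores(
                ens, match_fraction=1.0,
                max_features=int(cfg["pharmacophore"]["max_features"]))
            if joint:
                name = "joint_" + "_".join(pair)
                p = out / f"hypothesis_{name}.json"
                joint[0].to_json(p)
                manifest.record(f"hypothesis_{name}", p)

        align_path = out / "hypothesis_alignments.csv"
        with align_path.open("w") as fh:
            fh.write("reference,other,rmsd\n")
            names = sorted(hypotheses)
            for i, a in enumerate(names):
                for b in names[i + 1:]:
                    try:
                        al = align_hypotheses(hypotheses[a], hypotheses[b],
                                              reference_id=a, other_id=b)
                        fh.write(f"hyp-{a}-c,hyp-{b}-c,{al.rmsd:.4f}\n")
                    except AlignmentFailure:
                        fh.write(f"hyp-{a}-c,hyp-{b}-c,-\n")
        manifest.record("hypothesis_alignments", align_path)
        tick()

    manifest.save(out / "manifest.json")
    return manifest
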