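"""End-to-end orchestration: simulate -> prep -> (scan) -> fit -> metrics ->
states -> gradients -> graphs -> predict, from one config, with a provenance
manifest.

Each stage reads its inputs from and writes its outputs to a run directory,
so stages can be re-run in isolation; a single global seed fans out to fixed
per-stage child seeds, making every stochastic output reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as dio
from .cognition import (cluster_reduce_features, correlate_lesion_fo,
                        lesion_frequency_map, stepwise_regression,
                        univariate_group_tests)
from .dynamics import cohort_dynamics, compare_groups, pooled_transition_matrix
from .fc import compare_state_edges, sparsify_proportional
from .gradients import align_gradients, compute_gradients, reference_gradient
from .graphs import (compare_state_metrics, graph_metrics,
                     jaccard_partition_similarity, louvain_consensus)
from .hmm import GaussianHMM, HMMParams, decode_cohort, select_model_order, \
    state_correlation_matrix
from .preprocess import prep_subject, zscore_and_concat
from .simulate import (CONTROL, PATIENT, CognitiveSimConfig, SimConfig,
                       simulate_cohort, simulate_cognitive_scores,
                       simulate_lesions)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

STAGES = ("simulate", "prep", "scan", "fit", "metrics", "states",
          "gradients", "graphs", "predict")


@dataclass
class PipelineConfig:
    """All study-level settings of the analysis in one place."""

    seed: int = 0
    sim: dict = field(default_factory=dict)  # SimConfig overrides
    cognitive: dict = field(default_factory=dict)  # CognitiveSimConfig overrides
    K: int = 6
    K_range: list | None = None  # enables the order scan
    n_restarts: int = 5
    max_iter: int = 500
    tol: float = 1e-5
    truncate_last: int = 0
    cutoff_hz: float = 1.0 / 128.0
    sparsity: float = 0.80
    alpha_edge: float = 0.05
    alpha_fo: float = 0.01
    alpha_graph: float = 0.01
    alpha_univariate: float = 0.05
    n_gradients: int = 2
    row_sparsify: float = 0.5
    louvain_gamma: float = 1.0
    louvain_runs: int = 100
    louvain_tau: float = 0.5
    p_enter: float = 0.05
    p_remove: float = 0.10
    lesion_shape: tuple = (20, 24, 20)

    def __post_init__(self) -> None:
        for name in ("alpha_edge", "alpha_fo", "alpha_graph", "alpha_univariate"):
            a = getattr(self, name)
            if not 0.0 < a < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in {".yaml", ".yml"}:
            import yaml
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)

    def sim_config(self) -> SimConfig:
        return SimConfig(**{**self.sim, "seed": self._stage_seed("simulate")})

    def cognitive_config(self) -> CognitiveSimConfig:
        return CognitiveSimConfig(**self.cognitive)

    def _stage_seed(self, stage: str) -> int:
        child = np.random.SeedSequence(self.seed).spawn(len(STAGES))[STAGES.index(stage)]
        return int(child.generate_state(1)[0] % (2**31 - 1))


def _rd(run_dir) -> Path:
    p = Path(run_dir)
    p.mkdir(parents=True, exist_ok=True)
    return p


def stage_simulate(run_dir, config: PipelineConfig) -> list:
    """Generate the cohort, lesions and cognitive table with known truth."""
    run_dir = _rd(run_dir)
    sim = config.sim_config()
    subjects, gt = simulate_cohort(sim)
    files = []
    for sub in subjects:
        files += dio.write_subject(run_dir / "cohort", sub, seed=sim.seed)
    dio.write_ground_truth(run_dir / "ground_truth.json", gt)
    files.append(str(run_dir / "ground_truth.json"))

    rng = np.random.default_rng(config._stage_seed("simulate") + 1)
    patients = [s for s in subjects if s.group == PATIENT]
    # cognitive scores track the TRUE occupancy of the first pathological state
    from .dynamics import fractional_occupancy
    patho0 = gt.pathological_states[0]
    fo_true = np.array([fractional_occupancy(s.true_path, gt.K)[patho0 - 1]
                        for s in patients])
    cog = simulate_cognitive_scores(fo_true, config.cognitive_config(), rng)
    cog.insert(0, "subject_id", [s.subject_id for s in patients])
    cog.to_csv(run_dir / "cognitive.csv", index=False)
    files.append(str(run_dir / "cognitive.csv"))

    lesions = simulate_lesions(len(patients), rng, shape=tuple(config.lesion_shape))
    (run_dir / "lesions").mkdir(exist_ok=True)
    rows = []
    for sub, les in zip(patients, lesions):
        path = run_dir / "lesions" / f"{sub.subject_id}_lesion.nii.gz"
        dio.write_lesion_nifti(path, les)
        files.append(str(path))
        rows.append({"subject_id": sub.subject_id, "extension": les.extension,
                     "hemisphere": les.hemisphere})
    pd.DataFrame(rows).to_csv(run_dir / "lesions" / "lesions.tsv", sep="\t", index=False)
    files.append(str(run_dir / "lesions" / "lesions.tsv"))
    return files


def stage_prep(run_dir, config: PipelineConfig) -> list:
    """Denoise, harmonise, z-score and concatenate the cohort."""
    run_dir = _rd(run_dir)
    cohort_dir = run_dir / "cohort"
    subs = sorted(cohort_dir.glob("sub-*.tsv"))
    subs = [p for p in subs if not p.stem.endswith("_truepath")]
    cohort = [prep_subject(dio.read_subject(p), cutoff_hz=config.cutoff_hz)
              for p in subs]
    concat = zscore_and_concat(cohort, truncate_last=config.truncate_last)
    prep_dir = run_dir / "prep"
    prep_dir.mkdir(exist_ok=True)
    dio.write_matrix(prep_dir / "concat.tsv", concat.matrix)
    meta = {"ranges": concat.ranges, "subject_ids": concat.subject_ids,
            "groups": concat.groups, "TR": concat.TR}
    with open(prep_dir / "concat.json", "w") as fh:
        json.dump(meta, fh, indent=1)
    return [str(prep_dir / "concat.tsv"), str(prep_dir / "concat.json")]


def _load_concat(run_dir):
    run_dir = Path(run_dir)
    matrix = dio.read_matrix(run_dir / "prep" / "concat.tsv")
    with open(run_dir / "prep" / "concat.json") as fh:
        meta = json.load(fh)
    return matrix, [tuple(r) for r in meta["ranges"]], meta


def stage_scan(run_dir, config: PipelineConfig) -> list:
    """Model-order scan over the configured K range."""
    if not config.K_range:
        return []
    run_dir = _rd(run_dir)
    matrix, ranges, _ = _load_concat(run_dir)
    scan = select_model_order(matrix, ranges, K_range=config.K_range,
                              n_restarts=max(2, config.n_restarts // 2),
                              seed=config._stage_seed("scan"))
    out = run_dir / "scan"
    out.mkdir(exist_ok=True)
    scan.table.to_csv(out / "order_scan.tsv", sep="\t", index=False)
    with open(out / "recommended_K.json", "w") as fh:
        json.dump({"recommended_K": scan.recommended_K}, fh)
    return [str(out / "order_scan.tsv"), str(out / "recommended_K.json")]


def stage_fit(run_dir, config: PipelineConfig) -> list:
    run_dir = _rd(run_dir)
    matrix, ranges, _ = _load_concat(run_dir)
    res = GaussianHMM(matrix, ranges, config.K).fit(
        n_restarts=config.n_restarts, max_iter=config.max_iter, tol=config.tol,
        seed=config._stage_seed("fit"))
    out = run_dir / "hmm"
    out.mkdir(exist_ok=True)
    with open(out / "model.json", "w") as fh:
        json.dump({"K": res.params.K, "M": res.params.M,
                   "pi": res.params.pi.tolist(), "A": res.params.A.tolist(),
                   "mu": res.params.mu.tolist(), "loglik": res.loglik,
                   "BIC": res.bic, "converged": bool(res.converged)}, fh)
    files = [str(out / "model.json")]
    for k in range(config.K):
        dio.write_matrix(out / f"sigma_S{k + 1}.tsv", res.params.Sigma[k])
        files.append(str(out / f"sigma_S{k + 1}.tsv"))
    (out / "summary.txt").write_text(res.summary() + "\n")
    files.append(str(out / "summary.txt"))
    return files


def _load_model(run_dir, K: int) -> HMMParams:
    out = Path(run_dir) / "hmm"
    with open(out / "model.json") as fh:
        d = json.load(fh)
    Sigma = np.stack([dio.read_matrix(out / f"sigma_S{k + 1}.tsv")
                      for k in range(d["K"])])
    return HMMParams(pi=np.asarray(d["pi"]), A=np.asarray(d["A"]),
                     mu=np.asarray(d["mu"]), Sigma=Sigma)


def stage_metrics(run_dir, config: PipelineConfig) -> list:
    """Decode paths; per-subject FO/SR/transitions; group comparison."""
    run_dir = _rd(run_dir)
    matrix, ranges, meta = _load_concat(run_dir)
    params = _load_model(run_dir, config.K)
    paths = decode_cohort(params, matrix, ranges)
    mets = cohort_dynamics(paths, params.K, meta["TR"],
                           subject_ids=meta["subject_ids"], groups=meta["groups"])
    out = run_dir / "metrics"
    out.mkdir(exist_ok=True)
    rows = []
    for m in mets:
        row = {"subject_id": m.subject_id, "group": m.group, "SR_hz": m.SR,
               "max_fo_state": m.max_fo_state}
        row.update({f"FO_S{k + 1}": m.FO[k] for k in range(params.K)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "dynamics.tsv", sep="\t", index=False)
    table = compare_groups(mets, alpha=config.alpha_fo)
    table.to_csv(out / "group_tests.tsv", sep="\t", index=False)
    files = [str(out / "dynamics.tsv"), str(out / "group_tests.tsv")]
    for group in sorted(set(meta["groups"])):
        sel = [p for p, g in zip(paths, meta["groups"]) if g == group]
        T = pooled_transition_matrix(sel, params.K)
        dio.write_matrix(out / f"transitions_{group}.tsv", T)
        files.append(str(out / f"transitions_{group}.tsv"))
    np.savetxt(out / "paths.tsv", np.concatenate(paths)[:, None], fmt="%d")
    files.append(str(out / "paths.tsv"))
    return files


def _state_fcs(run_dir, config):
    params = _load_model(run_dir, config.K)
    mats = [state_correlation_matrix(params, k) for k in range(1, config.K + 1)]
    return [sparsify_proportional(R, config.sparsity, state=k + 1)
            for k, R in enumerate(mats)], mats


def stage_states(run_dir, config: PipelineConfig) -> list:
    """Sparsified state FC matrices and edge-strength comparisons."""
    run_dir = _rd(run_dir)
    sparse, dense = _state_fcs(run_dir, config)
    out = run_dir / "states"
    out.mkdir(exist_ok=True)
    files = []
    for k, (sp, R) in enumerate(zip(sparse, dense), start=1):
        dio.write_matrix(out / f"state_S{k}_fc.tsv", R)
        dio.write_matrix(out / f"state_S{k}_sparse.tsv", sp.R)
        iu = np.triu_indices(sp.M, k=1)
        trip = np.column_stack([iu[0][sp.mask[iu]], iu[1][sp.mask[iu]],
                                sp.R[iu][sp.mask[iu]]])
        np.savetxt(out / f"state_S{k}_mask.tsv", trip, delimiter="\t",
                   fmt=["%d", "%d", "%.8g"])
        files += [str(out / f"state_S{k}_fc.tsv"), str(out / f"state_S{k}_sparse.tsv"),
                  str(out / f"state_S{k}_mask.tsv")]
    table = compare_state_edges(sparse, alpha=config.alpha_edge)
    table.to_csv(out / "edge_tests.tsv", sep="\t", index=False)
    files.append(str(out / "edge_tests.tsv"))
    return files


def stage_gradients(run_dir, config: PipelineConfig) -> list:
    run_dir = _rd(run_dir)
    _, dense = _state_fcs(run_dir, config)
    sets = [compute_gradients(R, g=config.n_gradients,
                              row_sparsify=config.row_sparsify, state=k + 1)
            for k, R in enumerate(dense)]
    ref = reference_gradient(dense, g=config.n_gradients,
                             row_sparsify=config.row_sparsify)
    aligned, sim = align_gradients(sets, ref)
    out = run_dir / "gradients"
    out.mkdir(exist_ok=True)
    files = []
    for s in aligned:
        dio.write_matrix(out / f"state_S{s.state}_gradients.tsv", s.G)
        files.append(str(out / f"state_S{s.state}_gradients.tsv"))
    dio.write_matrix(out / "cosine_similarity.tsv", sim)
    files.append(str(out / "cosine_similarity.tsv"))
    return files


def stage_graphs(run_dir, config: PipelineConfig) -> list:
    run_dir = _rd(run_dir)
    sparse, _ = _state_fcs(run_dir, config)
    mets = [graph_metrics(sp.R, state=sp.state) for sp in sparse]
    out = run_dir / "graphs"
    out.mkdir(exist_ok=True)
    rows = []
    for m in mets:
        for i in range(m.degree.size):
            rows.append({"state": m.state, "node": i, "degree": m.degree[i],
                         "strength": m.strength[i], "betweenness": m.betweenness[i],
                         "clustering": m.clustering[i],
                         "local_efficiency": m.local_efficiency[i]})
    pd.DataFrame(rows).to_csv(out / "metrics.tsv", sep="\t", index=False)
    pd.DataFrame([{"state": m.state, "global_efficiency": m.global_efficiency}
                  for m in mets]).to_csv(out / "global_efficiency.tsv", sep="\t",
                                         index=False)
    tests = compare_state_metrics(mets, alpha=config.alpha_graph)
    tests.to_csv(out / "metric_tests.tsv", sep="\t", index=False)

    seed0 = config._stage_seed("graphs")
    parts = [louvain_consensus(sp.R, gamma=config.louvain_gamma,
                               n_runs=config.louvain_runs, tau=config.louvain_tau,
                               seed=seed0 + sp.state) for sp in sparse]
    pd.DataFrame([{"state": sp.state, "mean_Q": p.mean_Q, "consensus_Q": p.Q,
                   "n_modules": p.n_modules}
                  for sp, p in zip(sparse, parts)]).to_csv(
        out / "modularity.tsv", sep="\t", index=False)
    lab = np.column_stack([p.labels for p in parts])
    np.savetxt(out / "partitions.tsv", lab, delimiter="\t", fmt="%d",
               header="\t".join(f"S{sp.state}" for sp in sparse))
    K = len(parts)
    jac = np.ones((K, K))
    for a in range(K):
        for b in range(a + 1, K):
            jac[a, b] = jac[b, a] = jaccard_partition_similarity(parts[a], parts[b])
    dio.write_matrix(out / "jaccard.tsv", jac)
    return [str(out / f) for f in ("metrics.tsv", "global_efficiency.tsv",
                                   "metric_tests.tsv", "modularity.tsv",
                                   "partitions.tsv", "jaccard.tsv")]


def stage_predict(run_dir, config: PipelineConfig) -> list:
    """Patient stratification: lesions, univariate screening, feature
    reduction, stepwise regression on occupancy in each pathological state."""
    run_dir = _rd(run_dir)
    dyn = pd.read_csv(run_dir / "metrics" / "dynamics.tsv", sep="\t")
    with open(run_dir / "ground_truth.json") as fh:
        gt_meta = json.load(fh)
    patho = gt_meta["pathological_states"]
    pat = dyn[dyn["group"] == PATIENT].reset_index(drop=True)

    cog = pd.read_csv(run_dir / "cognitive.csv")
    cog = cog.set_index("subject_id").loc[pat["subject_id"]].reset_index()
    tests = cog.drop(columns=["subject_id"])

    lesions = pd.read_csv(run_dir / "lesions" / "lesions.tsv", sep="\t")
    lesions = lesions.set_index("subject_id").loc[pat["subject_id"]].reset_index()

    out = run_dir / "predict"
    out.mkdir(exist_ok=True)
    files = []

    rows = []
    for s in patho:
        r, p = correlate_lesion_fo(lesions["extension"], pat[f"FO_S{s}"])
        rows.append({"state": s, "pearson_r": r, "p": p})
    pd.DataFrame(rows).to_csv(out / "lesion_correlation.tsv", sep="\t", index=False)
    files.append(str(out / "lesion_correlation.tsv"))

    # subgroup = pathological state of maximal occupancy
    sub_labels = pat[[f"FO_S{s}" for s in patho]].to_numpy().argmax(axis=1)
    counts = np.bincount(sub_labels, minlength=len(patho))
    import nibabel as nib
    for j, s in enumerate(patho):
        ids = pat["subject_id"][sub_labels == j]
        masks = [np.asarray(nib.load(str(run_dir / "lesions" / f"{sid}_lesion.nii.gz"))
                            .dataobj) for sid in ids]
        if masks:
            freq = lesion_frequency_map(masks)
            img = nib.Nifti1Image(freq.astype(np.float32), affine=np.eye(4))
            nib.save(img, str(out / f"lesion_freq_S{s}.nii.gz"))
            files.append(str(out / f"lesion_freq_S{s}.nii.gz"))

    if len(patho) >= 2 and counts.min() >= 2:
        uni = univariate_group_tests(tests, sub_labels, alpha=config.alpha_univariate)
        uni.to_csv(out / "univariate.tsv", sep="\t", index=False)
        files.append(str(out / "univariate.tsv"))

    if len(pat) <= 3:
        logger.warning("too few patients (%d) for feature reduction and "
                       "stepwise regression; skipping models", len(pat))
        with open(out / "models.json", "w") as fh:
            json.dump({}, fh)
        files.append(str(out / "models.json"))
        return files

    models = {}
    for s in patho:
        y = pat[f"FO_S{s}"].to_numpy()
        selected = cluster_reduce_features(tests, y)
        model = stepwise_regression(tests[selected], y, p_enter=config.p_enter,
                                    p_remove=config.p_remove)
        models[f"S{s}"] = {"clustered_features": selected,
                           "selected": model.selected,
                           "beta": model.beta.to_dict(),
                           "intercept": model.intercept,
                           "r_squared": model.r_squared}
    with open(out / "models.json", "w") as fh:
        json.dump(models, fh, indent=1)
    files.append(str(out / "models.json"))
    return files


STAGE_FUNCS = {
    "simulate": stage_simulate, "prep": stage_prep, "scan": stage_scan,
    "fit": stage_fit, "metrics": stage_metrics, "states": stage_states,
    "gradients": stage_gradients, "graphs": stage_graphs, "predict": stage_predict,
}


def run_pipeline(config: PipelineConfig, run_dir) -> Path:
    """Execute all stages in order and write a provenance manifest.

    Any stage failure halts the run with the stage name; outputs of earlier
    stages are preserved. Re-running with the same config and seed
    reproduces every output bit-identically.
    """
    run_dir = _rd(run_dir)
    manifest = {"config": asdict(config), "seed": config.seed, "files": {}}
    for stage in STAGES:
        logger.info("stage %s", stage)
        try:
            files = STAGE_FUNCS[stage](run_dir, config)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        for f in files:
            manifest["files"][str(Path(f).relative_to(run_dir))] = dio.sha256_of(f)
    with open(run_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return run_dir
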