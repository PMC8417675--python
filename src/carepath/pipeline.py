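"""End-to-end pipeline: simulate → cohort → cluster → mine → features →
model, with plain-file stage outputs, a run manifest, and resumable stages.

Each stage reads and writes ordinary CSV/TSV/GeoJSON/JSON files under the
run directory, so every stage is independently inspectable and testable.
Re-running with an identical configuration reproduces identical outputs;
under ``resume=True`` completed stages are skipped.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import builtenv, clustering, cohort, lcs, models, simdata, spade

__all__ = ["DEFAULT_RUN_CONFIG", "run_pipeline", "report", "config_hash"]

STAGES = ["simulate", "cohort", "cluster", "mine", "features", "model"]

DEFAULT_RUN_CONFIG: dict = {
    "seed": 0,
    "stages": STAGES,
    "sim": {},  # SimConfig overrides
    "ppd_codes": [simdata.PPD_CODE],
    "vocabulary": None,  # None -> the simulation vocabulary
    "distance_norm": "max",
    "linkage": "average",
    "k_range": [2, 8],
    "write_distances": False,
    "minsup": 0.10,
    "max_len": 5,
    "use_istep": True,
    "buffer_r": 500.0,
    "model": {"mediator_covariates": ["lum_500", "retfar_250", "pm25", "gini", "college_pct", "age", "married"],
              "reference_cluster": None,  # None -> largest cluster... set at run time to last label
              "n_imputations": 5, "n_iter": 10, "vif_threshold": 10.0},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _stage_done(out: Path, stage: str) -> bool:
    markers = {
        "simulate": out / "sim" / "patients.csv",
        "cohort": out / "cohort" / "sequences.csv",
        "cluster": out / "cluster" / "labels.csv",
        "mine": out / "patterns" / "patterns.tsv",
        "features": out / "features" / "built_env.csv",
        "model": out / "model" / "outcome_eq.tsv",
    }
    return markers[stage].exists()


def _load_sequences(path: Path) -> dict[str, cohort.PatientSequence]:
    df = pd.read_csv(path)
    seqs: dict[str, cohort.PatientSequence] = {}
    for pid, grp in df.groupby("patient_id", sort=True):
        seqs[str(pid)] = cohort.PatientSequence(str(pid), list(grp["code"]), [int(t) for t in grp["t"]])
    return seqs


def run_pipeline(config: dict | None = None, out_dir: str | Path = "run", resume: bool = False) -> dict:
    """Execute the enabled stages in order and return the run manifest."""
    cfg = _merge(DEFAULT_RUN_CONFIG, config or {})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": config_hash(cfg), "stages": {}, "version": 1}
    enabled = [s for s in STAGES if s in cfg["stages"]]

    for stage in enabled:
        if resume and _stage_done(out, stage):
            manifest["stages"][stage] = {"skipped": True}
            continue
        t0 = time.time()
        counters = _STAGE_FNS[stage](cfg, out)
        counters["seconds"] = round(time.time() - t0, 2)
        manifest["stages"][stage] = counters

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def _stage_simulate(cfg: dict, out: Path) -> dict:
    sim_cfg = simdata.SimConfig.from_dict({"seed": cfg["seed"], **cfg["sim"]})
    bundle = simdata.simulate_study(sim_cfg)
    simdata.write_bundle(bundle, out / "sim")
    return {"patients": len(bundle.patients), "events": len(bundle.events)}


def _stage_cohort(cfg: dict, out: Path) -> dict:
    sim = out / "sim"
    patients = pd.read_csv(sim / "patients.csv")
    events = pd.read_csv(sim / "events.csv")
    kept, kept_events, tally = cohort.apply_inclusion_exclusion(patients, events)
    ppd = cohort.label_ppd(kept_events, set(cfg["ppd_codes"]))
    kept = kept.merge(ppd.rename("ppd"), left_on="patient_id", right_index=True, how="left")
    kept["ppd"] = kept["ppd"].fillna(False).astype(bool)
    vocab = cfg["vocabulary"]
    if vocab is None:
        sim_cfg = simdata.SimConfig.from_dict({"seed": cfg["seed"], **cfg["sim"]})
        vocab = sim_cfg.tokens
    seqs, n_dropped = cohort.build_sequences(kept_events, vocab)
    summ = cohort.cohort_summary(kept, kept_events)

    cdir = out / "cohort"
    cdir.mkdir(exist_ok=True)
    kept.to_csv(cdir / "patients.csv", index=False)
    kept_events.to_csv(cdir / "events.csv", index=False)
    rows = [(s.patient_id, t, tok) for s in seqs.values() for tok, t in zip(s.tokens, s.times)]
    pd.DataFrame(rows, columns=["patient_id", "t", "code"]).to_csv(cdir / "sequences.csv", index=False)
    with open(cdir / "exclusions.json", "w") as fh:
        json.dump({**tally, "sequence_dropped_no_allowed_tokens": n_dropped}, fh, indent=2)
    with open(cdir / "cohort_summary.tsv", "w") as fh:
        fh.write(f"n\t{summ.n}\n")
        for var, row in summ.continuous.iterrows():
            fh.write(f"{var}\tmean (SD)\t{row['mean']:.2f} ({row['sd']:.2f})\n")
        for _, r in summ.categorical.iterrows():
            fh.write(f"{r['variable']}={r['level']}\tN (%)\t{r['n']} ({r['pct']:.2f})\n")
        for k, v in summ.extras.items():
            fh.write(f"{k}\t%\t{v:.2f}\n")
    return {"patients_in": len(patients), "patients_kept": len(kept), **tally}


def _stage_cluster(cfg: dict, out: Path) -> dict:
    seqs = _load_sequences(out / "cohort" / "sequences.csv")
    ids, D = lcs.pairwise_distance_matrix(seqs, norm=cfg["distance_norm"])
    lo, hi = cfg["k_range"]
    res = clustering.silhouette_and_select_k(D, k_range=range(lo, hi + 1), method=cfg["linkage"], ids=ids)
    cdir = out / "cluster"
    cdir.mkdir(exist_ok=True)
    pd.DataFrame({"patient_id": ids, "cluster": res.labels}).to_csv(cdir / "labels.csv", index=False)
    with open(cdir / "silhouette.json", "w") as fh:
        json.dump({"k": res.k, "linkage": res.linkage,
                   "silhouette_by_k": {str(k): v for k, v in res.silhouette_by_k.items()}}, fh, indent=2)
    if cfg["write_distances"]:
        pd.DataFrame(D, index=ids, columns=ids).to_csv(cdir / "distances.csv")
    return {"n_sequences": len(ids), "k_selected": res.k}


def _stage_mine(cfg: dict, out: Path) -> dict:
    seqs = _load_sequences(out / "cohort" / "sequences.csv")
    labels = pd.read_csv(out / "cluster" / "labels.csv")
    lab = dict(zip(labels["patient_id"].astype(str), labels["cluster"]))
    patients = pd.read_csv(out / "cohort" / "patients.csv")
    ppd = dict(zip(patients["patient_id"].astype(str), patients["ppd"].astype(bool)))
    db = spade.from_patient_sequences(seqs)
    per_cluster = spade.mine_per_cluster(
        db, lab, minsup=cfg["minsup"], max_len=cfg["max_len"], ppd_labels=ppd, use_istep=cfg["use_istep"]
    )
    pdir = out / "patterns"
    pdir.mkdir(exist_ok=True)
    rows = []
    for cl, pats in per_cluster.items():
        for p in pats:
            rows.append({"cluster": cl, "pattern": str(p), "support": p.support,
                         "support_frac": round(p.support_frac, 4),
                         "ppd_n": p.outcome_split[0], "no_ppd_n": p.outcome_split[1]})
    pd.DataFrame(rows, columns=["cluster", "pattern", "support", "support_frac", "ppd_n", "no_ppd_n"]).to_csv(
        pdir / "patterns.tsv", sep="\t", index=False
    )
    for cl, pats in per_cluster.items():
        (pdir / f"cluster_{cl}.dot").write_text(spade.patterns_to_dot(pats, title=f"cluster {cl}"))
    return {"patterns_total": len(rows), "clusters": len(per_cluster)}


def _stage_features(cfg: dict, out: Path) -> dict:
    patients = pd.read_csv(out / "cohort" / "patients.csv")
    layers = builtenv.load_layers(out / "sim" / "layers")
    tracts = pd.read_csv(out / "sim" / "tracts.csv")
    feats = builtenv.assemble_features(patients, layers, tracts, r=cfg["buffer_r"])
    fdir = out / "features"
    fdir.mkdir(exist_ok=True)
    feats.to_csv(fdir / "built_env.csv", index=False)
    return {"patients": len(feats), "lum_missing": int(feats["lum_500"].isna().sum())}


def _stage_model(cfg: dict, out: Path) -> dict:
    patients = pd.read_csv(out / "cohort" / "patients.csv")
    feats = pd.read_csv(out / "features" / "built_env.csv")
    labels = pd.read_csv(out / "cluster" / "labels.csv")
    df = patients.merge(feats, on="patient_id").merge(labels, on="patient_id")
    df["married"] = (df["marital"] == "married").astype(float)
    mcfg = cfg["model"]
    ref = mcfg["reference_cluster"]
    if ref is None:
        # reference = the cluster with the lowest PPD rate (the routine-care analogue)
        ref = int(df.groupby("cluster")["ppd"].mean().idxmin())

    covs = [c for c in mcfg["mediator_covariates"] if c in df.columns]
    work = df[["patient_id", "cluster", "ppd", *covs]].copy()
    work["ppd"] = work["ppd"].astype(float)
    missing_cols = [c for c in covs if work[c].isna().any()]
    imputed = models.chained_imputation(
        work[["cluster", "ppd", *covs]], m=mcfg["n_imputations"], n_iter=mcfg["n_iter"], seed=cfg["seed"],
        columns=missing_cols or None,
    ) if missing_cols else None

    retained, vifs = models.vif_screen(work[covs].fillna(work[covs].mean()), threshold=mcfg["vif_threshold"])
    spec = models.ModelSpec(mediator_covariates=retained, reference_cluster=ref,
                            vif_threshold=mcfg["vif_threshold"], n_imputations=mcfg["n_imputations"])
    base = work[["cluster", "ppd", *covs]]
    fit = models.fit_path_model(base, spec, imputed=imputed)

    compare_vars = [c for c in ("age", "bmi", "marital", "race", "insurance", "ppd") if c in df.columns]
    cmp_df = df[compare_vars].copy()
    if "ppd" in cmp_df:
        cmp_df["ppd"] = cmp_df["ppd"].astype(bool).astype(object)
    comparison = models.group_compare(cmp_df, df["cluster"].to_numpy(), variables=compare_vars)
    env_vars = [c for c in feats.columns if c not in ("patient_id", "gini")]
    env_df = df[["gini", *env_vars]].fillna(df[["gini", *env_vars]].mean())
    assoc = models.unadjusted_env_associations(env_df, df["ppd"].astype(float), variables=env_vars)

    mdir = out / "model"
    mdir.mkdir(exist_ok=True)
    fit.mediator_eq.to_csv(mdir / "mediator_eq.tsv", sep="\t", index=False)
    fit.outcome_eq.to_csv(mdir / "outcome_eq.tsv", sep="\t", index=False)
    comparison.to_csv(mdir / "group_compare.tsv", sep="\t", index=False)
    assoc.to_csv(mdir / "env_associations.tsv", sep="\t", index=False)
    with open(mdir / "vif.json", "w") as fh:
        json.dump({"retained": retained, "vif": vifs, "reference_cluster": ref}, fh, indent=2)
    return {"n_model": fit.n_used, "m": fit.m, "converged": fit.converged, "reference_cluster": ref}


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "cohort": _stage_cohort,
    "cluster": _stage_cluster,
    "mine": _stage_mine,
    "features": _stage_features,
    "model": _stage_model,
}


def report(run_dir: str | Path) -> str:
    """Human-readable summary of a completed run: cohort, cluster sizes and
    PPD rates, top patterns per cluster, and the model odds-ratio tables."""
    out = Path(run_dir)
    lines = []
    cs = out / "cohort" / "cohort_summary.tsv"
    if not cs.exists():
        raise FileNotFoundError("cohort stage output missing (cohort_summary.tsv)")
    lines.append("== Cohort ==")
    lines.append(cs.read_text().rstrip())
    labels_path = out / "cluster" / "labels.csv"
    if labels_path.exists():
        labels = pd.read_csv(labels_path)
        patients = pd.read_csv(out / "cohort" / "patients.csv")
        merged = patients.merge(labels, on="patient_id")
        lines.append("\n== Clusters ==")
        for cl, grp in merged.groupby("cluster"):
            lines.append(f"cluster {cl}: n={len(grp)}, PPD rate={100 * grp['ppd'].mean():.2f}%")
    pat_path = out / "patterns" / "patterns.tsv"
    if pat_path.exists():
        pats = pd.read_csv(pat_path, sep="\t")
        lines.append("\n== Top patterns per cluster ==")
        if len(pats) == 0:
            lines.append("no frequent patterns")
        else:
            for cl, grp in pats.groupby("cluster"):
                top = grp.sort_values(["support", "pattern"], ascending=[False, True]).head(5)
                for _, r in top.iterrows():
                    lines.append(f"cluster {cl}: {r['pattern']}  support={r['support']} (PPD {r['ppd_n']}/{r['support']})")
    for name, path in (("Mediator equation", out / "model" / "mediator_eq.tsv"),
                       ("Outcome equation", out / "model" / "outcome_eq.tsv")):
        if path.exists():
            lines.append(f"\n== {name} ==")
            lines.append(path.read_text().rstrip())
    text = "\n".join(lines) + "\n"
    (out / "report.txt").write_text(text)
    return text
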