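"""Stage orchestration: file-based pipeline over the library modules.

Each stage reads its inputs from files in the working directory, runs one
library stage and writes its outputs plus a JSON manifest (parameters,
input hashes, package version), so every stage is runnable standalone and
deterministic stages are bit-reproducible.  Stage order on a synthetic
run: simulate -> qc -> peaks -> modules -> links -> grn -> te -> loss.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, cre_modules, fragment_qc, grn, io, linkage, peak_filter
from . import seqmodel_loss, simulate, te_conservation

__all__ = ["PipelineConfig", "run_stage", "STAGES"]

_STAGE_PARAM_KEYS = {
    "simulate": set(f.name for f in dataclasses.fields(simulate.SimulationConfig)),
    "fragments": set(f.name for f in dataclasses.fields(simulate.FragmentConfig)),
    "grn_sim": set(f.name for f in dataclasses.fields(simulate.GrnConfig)),
    "qc": {"min_fragments", "min_tsse"},
    "peaks": {"flank", "min_spm", "min_overlap", "fdr"},
    "modules": {"rank", "max_iter", "tol"},
    "links": {"window", "proximal_margin", "metacell_size", "coaccess_fdr", "link_fdr"},
    "grn": {"p_max", "top_k", "n_bags", "ridge_penalty"},
    "te": {"min_fraction"},
    "loss": {"mode", "reduction"},
}


@dataclass
class PipelineConfig:
    """Per-stage parameters, paths and the master seed.

    Unknown keys (top-level or within a stage block) are rejected; the
    effective config is serialized into the output directory.
    """

    seed: int = 0
    outdir: str = "atlas_out"
    simulate: dict = field(default_factory=dict)
    fragments: dict = field(default_factory=dict)
    grn_sim: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)
    peaks: dict = field(default_factory=dict)
    modules: dict = field(default_factory=dict)
    links: dict = field(default_factory=dict)
    grn: dict = field(default_factory=dict)
    te: dict = field(default_factory=dict)
    loss: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for stage, allowed in _STAGE_PARAM_KEYS.items():
            extra = set(getattr(self, stage)) - allowed
            if extra:
                raise ValueError(f"unknown keys in config block {stage!r}: {sorted(extra)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(data) - known
        if extra:
            raise ValueError(f"unknown config keys: {sorted(extra)}")
        return cls(**data)

    @property
    def out(self) -> Path:
        return Path(self.outdir)


def _manifest(cfg: PipelineConfig, stage: str, params: dict, inputs: list, outputs: list) -> None:
    manifest = {
        "stage": stage,
        "version": __version__,
        "seed": cfg.seed,
        "params": params,
        "inputs": {str(p): io.sha256_file(p) for p in inputs},
        "outputs": [str(p) for p in outputs],
    }
    io.write_json(manifest, cfg.out / f"manifest_{stage}.json")


def _require(cfg: PipelineConfig, path: Path, producer: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"missing input {path}; run the {producer!r} stage first")
    return path


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(cfg: PipelineConfig) -> list:
    out = cfg.out
    out.mkdir(parents=True, exist_ok=True)
    sim = simulate.SimulationConfig(seed=cfg.seed, **cfg.simulate)
    X, expression, truth = simulate.make_atlas(sim)

    peak_ids = truth.peaks["peak_id"].tolist()
    cell_ids = [f"cell{i}" for i in range(X.shape[0])]
    io.write_matrix(X, cell_ids, peak_ids, out / "cellpeak")
    io.write_bed(truth.peaks, out / "peaks.bed", columns=["chrom", "start", "end", "peak_id", "summit"])
    pd.DataFrame({"cell": cell_ids, "subclass": truth.subclass_of_cell}).to_csv(
        out / "subclasses.tsv", sep="\t", index=False
    )
    expression.to_csv(out / "expression.tsv", sep="\t")
    truth.genes.to_csv(out / "genes.tsv", sep="\t", index=False)

    calls = simulate.make_summit_calls(truth, sim)
    frames = []
    for cluster, sets in calls.items():
        for rep, df in sets.items():
            f = df.copy()
            f.insert(0, "replicate", rep)
            f.insert(0, "cluster", cluster)
            frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(out / "summits.tsv", sep="\t", index=False)

    # background cell fractions at random non-peak regions: Bernoulli noise
    rng = simulate.stream_rng(cfg.seed, "atlas")
    n_bg = 2000
    bg = rng.binomial(
        sim.n_cells_per_subclass, sim.background_rate, size=(n_bg, sim.n_subclasses)
    ) / sim.n_cells_per_subclass
    pd.DataFrame(bg, columns=[f"subclass{s}" for s in range(sim.n_subclasses)]).to_csv(
        out / "background_fractions.tsv", sep="\t", index=False
    )

    frag_cfg = simulate.FragmentConfig(seed=cfg.seed, **cfg.fragments)
    fragments, tss, barcode_truth = simulate.make_fragments(frag_cfg)
    io.write_fragments(fragments, out / "fragments.tsv")
    tss_bed = pd.DataFrame(
        {
            "chrom": tss["chrom"],
            "start": np.where(tss["strand"] == "+", tss["pos"], tss["pos"]),
            "end": np.where(tss["strand"] == "+", tss["pos"] + 1, tss["pos"] + 1),
            "name": [f"tss{i}" for i in range(len(tss))],
            "score": 0,
            "strand": tss["strand"],
        }
    )
    io.write_bed(tss_bed, out / "tss.bed", columns=["chrom", "start", "end", "name", "score", "strand"])
    barcode_truth.to_csv(out / "barcode_truth.tsv", sep="\t", index=False)

    grn_cfg = simulate.GrnConfig(seed=cfg.seed, **cfg.grn_sim)
    grn_truth, grn_expr = simulate.make_grn_truth(grn_cfg)
    grn_expr.to_csv(out / "grn_expression.tsv", sep="\t", index=False)
    grn_truth.edges.to_csv(out / "grn_truth_edges.tsv", sep="\t", index=False)
    tf_names = [n for n in grn_truth.node_names if n.startswith("tf")]
    pd.DataFrame(
        {
            "target": [n for n in grn_truth.node_names if not n.startswith("tf")],
            "regulators": ",".join(tf_names),
        }
    ).to_csv(out / "grn_candidates.tsv", sep="\t", index=False)

    te_fracs, is_high = simulate.make_te_fractions(sim)
    pd.DataFrame(
        {
            "subclass": [f"subclass{s}" for s in range(sim.n_subclasses)],
            "te_fraction": te_fracs,
            "is_high_truth": is_high,
        }
    ).to_csv(out / "te_fractions.tsv", sep="\t", index=False)

    io.write_json(
        {
            "module_of_peak": truth.module_of_peak,
            "planted_links": truth.planted_links.to_dict(orient="list"),
            "highte_subclasses": truth.highte_subclasses,
            "te_label_of_peak": list(truth.te_label_of_peak),
        },
        out / "truth.json",
    )
    outputs = sorted(p for p in out.iterdir() if p.is_file())
    _manifest(cfg, "simulate", dataclasses.asdict(sim), [], outputs)
    return outputs


def _stage_qc(cfg: PipelineConfig) -> list:
    out = cfg.out
    frag_path = _require(cfg, out / "fragments.tsv", "simulate")
    tss_path = _require(cfg, out / "tss.bed", "simulate")
    fragments = io.read_fragments(frag_path)
    tss = io.read_tss_bed(tss_path)
    params = {"min_fragments": 1000, "min_tsse": 10.0, **cfg.qc}
    qc = fragment_qc.qc_table(fragments, tss, **params)
    qc.to_csv(out / "qc.tsv", sep="\t", index=False)
    _manifest(cfg, "qc", params, [frag_path, tss_path], [out / "qc.tsv"])
    return [out / "qc.tsv"]


def _stage_peaks(cfg: PipelineConfig) -> list:
    out = cfg.out
    summits_path = _require(cfg, out / "summits.tsv", "simulate")
    bg_path = _require(cfg, out / "background_fractions.tsv", "simulate")
    params = {"flank": 250, "min_spm": 5.0, "min_overlap": 0.5, "fdr": 0.01, **cfg.peaks}
    summits = pd.read_csv(summits_path, sep="\t")

    per_cluster = {}
    for cluster, group in summits.groupby("cluster"):
        sets = {
            rep: peak_filter.extend_summits(g.drop(columns=["cluster", "replicate"]), flank=params["flank"])
            for rep, g in group.groupby("replicate")
        }
        pooled = peak_filter.spm_transform(sets["pooled"])
        repro = peak_filter.reproducible_peaks(
            pooled,
            sets.get("rep1"),
            sets.get("rep2"),
            sets.get("pseudo1"),
            sets.get("pseudo2"),
            min_overlap=params["min_overlap"],
        )
        per_cluster[cluster] = peak_filter.spm_filter(repro, min_spm=params["min_spm"])
    catalogue = peak_filter.merge_union(per_cluster)

    blacklist_path = out / "blacklist.bed"
    if blacklist_path.exists():
        catalogue = peak_filter.blacklist_filter(catalogue, io.read_bed(blacklist_path))

    # cell-fraction filter against the background-region null
    X, cells, peak_ids = io.read_matrix(out / "cellpeak")
    peaks_bed = io.read_bed(out / "peaks.bed", names=("chrom", "start", "end", "peak_id", "summit"))
    subclasses = pd.read_csv(out / "subclasses.tsv", sep="\t")["subclass"].to_numpy()
    by_coord = {
        (c, s): pid
        for c, s, pid in zip(peaks_bed["chrom"], peaks_bed["summit"], peaks_bed["peak_id"])
    }
    catalogue["peak_id"] = [
        by_coord.get((c, s), "") for c, s in zip(catalogue["chrom"], catalogue["summit"])
    ]
    known = catalogue["peak_id"] != ""
    cat_known = catalogue[known].reset_index(drop=True)
    col_of = {pid: j for j, pid in enumerate(peak_ids)}
    cols = [col_of[p] for p in cat_known["peak_id"]]
    Xc = X.tocsc()[:, cols]
    n_sub = subclasses.max() + 1
    frac = np.zeros((len(cols), n_sub))
    for s in range(n_sub):
        rows = np.nonzero(subclasses == s)[0]
        frac[:, s] = np.asarray((Xc[rows] > 0).sum(axis=0)).ravel() / len(rows)
    fractions = pd.DataFrame(
        frac, index=cat_known["peak_id"], columns=[f"subclass{s}" for s in range(n_sub)]
    )
    background = pd.read_csv(bg_path, sep="\t").to_numpy().ravel()
    null = peak_filter.fit_zib(background)
    retained, _ = peak_filter.zib_filter(fractions, null, fdr=params["fdr"])
    final = cat_known[cat_known["peak_id"].isin(retained.index)].reset_index(drop=True)

    io.write_bed(
        final,
        out / "catalogue.bed",
        columns=["chrom", "start", "end", "peak_id", "spm", "source_clusters"],
    )
    _manifest(cfg, "peaks", params, [summits_path, bg_path], [out / "catalogue.bed"])
    return [out / "catalogue.bed"]


def _pseudobulk(X, subclasses: np.ndarray) -> np.ndarray:
    n_sub = subclasses.max() + 1
    out = np.zeros((n_sub, X.shape[1]))
    Xr = X.tocsr()
    for s in range(n_sub):
        rows = np.nonzero(subclasses == s)[0]
        out[s] = np.asarray(Xr[rows].sum(axis=0)).ravel()
    return out


def _read_catalogue(cfg: PipelineConfig):
    out = cfg.out
    path = _require(cfg, out / "catalogue.bed", "peaks")
    cat = io.read_bed(path, names=("chrom", "start", "end", "peak_id", "spm", "source_clusters"))
    cat["summit"] = cat["start"] + 250
    X, cells, peak_ids = io.read_matrix(out / "cellpeak")
    subclasses = pd.read_csv(out / "subclasses.tsv", sep="\t")["subclass"].to_numpy()
    col_of = {pid: j for j, pid in enumerate(peak_ids)}
    cols = [col_of[p] for p in cat["peak_id"]]
    return cat, X.tocsc()[:, cols].tocsr(), subclasses, path


def _stage_modules(cfg: PipelineConfig) -> list:
    out = cfg.out
    cat, Xc, subclasses, cat_path = _read_catalogue(cfg)
    params = {"rank": 8, "max_iter": 400, "tol": 1e-6, **cfg.modules}
    V = cre_modules.cpm_normalize(_pseudobulk(Xc, subclasses).T)  # peaks x subclasses
    dec = cre_modules.nmf(V, params["rank"], seed=cfg.seed, max_iter=params["max_iter"], tol=params["tol"])
    scores, selected = cre_modules.feature_scores(dec.W)
    scaled, assoc, flagged = cre_modules.associate_modules(dec.H)
    pd.DataFrame(dec.W, index=cat["peak_id"]).to_csv(out / "nmf_W.tsv", sep="\t")
    pd.DataFrame(dec.H).to_csv(out / "nmf_H.tsv", sep="\t")
    assignment = cre_modules.module_of_peak(dec.W)
    io.write_json(
        {
            "rank": params["rank"],
            "reconstruction_error": dec.error,
            "converged": dec.converged,
            "module_sizes": np.bincount(assignment, minlength=params["rank"]),
            "n_module_specific": int(selected.sum()),
            "flagged_columns": flagged,
        },
        out / "modules_report.json",
    )
    module_peaks = cat[selected].copy()
    module_peaks["module"] = assignment[selected]
    io.write_bed(module_peaks, out / "module_peaks.bed",
                 columns=["chrom", "start", "end", "peak_id", "module"])
    _manifest(cfg, "modules", params, [cat_path],
              [out / "nmf_W.tsv", out / "nmf_H.tsv", out / "modules_report.json", out / "module_peaks.bed"])
    return [out / "nmf_W.tsv", out / "nmf_H.tsv", out / "module_peaks.bed"]


def _stage_links(cfg: PipelineConfig) -> list:
    out = cfg.out
    cat, Xc, subclasses, cat_path = _read_catalogue(cfg)
    genes = pd.read_csv(_require(cfg, out / "genes.tsv", "simulate"), sep="\t")
    expression = pd.read_csv(out / "expression.tsv", sep="\t", index_col=0)
    params = {
        "window": 500_000,
        "proximal_margin": 1000,
        "metacell_size": 10,
        "coaccess_fdr": 0.001,
        "link_fdr": 0.01,
        **cfg.links,
    }
    tss = genes.rename(columns={"tss": "pos"})[["chrom", "pos", "strand", "gene"]]
    pairs = linkage.enumerate_pairs(
        cat, tss, window=params["window"], proximal_margin=params["proximal_margin"]
    )
    rng = np.random.default_rng(cfg.seed)
    meta = linkage.make_metacells(Xc, subclasses, params["metacell_size"], rng)
    scores, _ = linkage.score_coaccessibility(meta, pairs)
    meta_shuf = linkage.make_metacells(
        linkage.shuffle_peak_columns(Xc.tocsc(), rng), subclasses, params["metacell_size"], rng
    )
    shuffled, _ = linkage.score_coaccessibility(meta_shuf, pairs)
    retained, qvals, null = linkage.calibrate_coaccess_null(
        scores, shuffled[np.isfinite(shuffled)], fdr=params["coaccess_fdr"]
    )
    pairs = pairs.assign(score=scores, qvalue=qvals, significant=retained)
    pairs.to_csv(out / "coaccess_pairs.tsv", sep="\t", index=False)

    # enhancer-gene candidates: every distal-proximal pair in the window
    dp = pairs[pairs["class"] == "distal-proximal"].copy()
    # orient: which member is proximal; its gene is the nearest TSS's gene
    gene_links = _pairs_to_gene_links(dp, cat, tss, params["proximal_margin"])
    access = pd.DataFrame(
        _pseudobulk(Xc, subclasses),
        index=expression.index,
        columns=cat["peak_id"],
    )
    scored = linkage.link_enhancer_gene(access, expression, gene_links)
    real = scored["pcc"].to_numpy()
    rng2 = np.random.default_rng(cfg.seed + 1)
    shuffled_links = scored.copy()
    shuffled_links["gene"] = rng2.permutation(scored["gene"].to_numpy())
    shuf_pcc = linkage.link_enhancer_gene(access, expression, shuffled_links)["pcc"].to_numpy()
    pos_t, neg_t, cls = linkage.empirical_fdr(real, shuf_pcc[np.isfinite(shuf_pcc)], fdr=params["link_fdr"])
    scored["sign"] = cls
    scored.to_csv(out / "links.tsv", sep="\t", index=False)
    io.write_json(
        {
            "n_pairs": len(pairs),
            "n_significant_pairs": int(retained.sum()),
            "null_mu": null.mu,
            "null_sigma": null.sigma,
            "pos_threshold": pos_t,
            "neg_threshold": neg_t,
            "n_positive_links": int((cls == 1).sum()),
            "n_negative_links": int((cls == -1).sum()),
        },
        out / "links_report.json",
    )
    _manifest(cfg, "links", params, [cat_path], [out / "links.tsv", out / "links_report.json"])
    return [out / "links.tsv"]


def _pairs_to_gene_links(dp: pd.DataFrame, cat: pd.DataFrame, tss: pd.DataFrame, margin: int) -> pd.DataFrame:
    """Orient distal-proximal pairs into (distal peak, gene) candidates."""
    summit = cat["summit"].to_numpy()
    chrom = cat["chrom"].to_numpy()
    tss_by_chrom = {c: g.sort_values("pos") for c, g in tss.groupby("chrom")}

    def gene_at(i):
        g = tss_by_chrom.get(chrom[i])
        if g is None:
            return None
        d = np.abs(g["pos"].to_numpy() - summit[i])
        j = int(np.argmin(d))
        return g["gene"].iloc[j] if d[j] <= margin else None

    rows = []
    for _, row in dp.iterrows():
        a, b = int(row["a"]), int(row["b"])
        ga, gb = gene_at(a), gene_at(b)
        if ga is not None and gb is None:
            rows.append((cat["peak_id"].iat[b], ga, row["distance"]))
        elif gb is not None and ga is None:
            rows.append((cat["peak_id"].iat[a], gb, row["distance"]))
    return pd.DataFrame(rows, columns=["peak", "gene", "distance"]).drop_duplicates(
        subset=["peak", "gene"]
    ).reset_index(drop=True)


def _stage_grn(cfg: PipelineConfig) -> list:
    out = cfg.out
    expr_path = _require(cfg, out / "grn_expression.tsv", "simulate")
    cand_path = _require(cfg, out / "grn_candidates.tsv", "simulate")
    expression = pd.read_csv(expr_path, sep="\t")
    cand = pd.read_csv(cand_path, sep="\t")
    candidates = {
        row["target"]: row["regulators"].split(",") for _, row in cand.iterrows()
    }
    params = {"p_max": 0.001, "top_k": 10_000, "n_bags": 20, "ridge_penalty": 1.0, **cfg.grn}
    net = grn.infer_grn(expression, candidates, seed=cfg.seed, **params)
    net.edges.to_csv(out / "grn_edges.tsv", sep="\t", index=False)
    grn.count_motifs(net).to_csv(out / "grn_motifs.tsv", sep="\t", index=False)
    grn.eigenvector_centrality(net).to_csv(out / "grn_centrality.tsv", sep="\t")
    try:
        fit = grn.degree_powerlaw_check(net, seed=cfg.seed)
        powerlaw = {"alpha": fit.alpha, "xmin": fit.xmin, "ks": fit.ks,
                    "plausible": fit.plausible, "fittable": fit.fittable}
    except ValueError as exc:
        powerlaw = {"error": str(exc)}
    io.write_json({"n_edges": len(net.edges), "powerlaw": powerlaw}, out / "grn_report.json")
    _manifest(cfg, "grn", params, [expr_path, cand_path],
              [out / "grn_edges.tsv", out / "grn_motifs.tsv", out / "grn_centrality.tsv"])
    return [out / "grn_edges.tsv"]


def _stage_te(cfg: PipelineConfig) -> list:
    out = cfg.out
    frac_path = _require(cfg, out / "te_fractions.tsv", "simulate")
    fracs = pd.read_csv(frac_path, sep="\t")
    fit = te_conservation.fit_highte_mixture(fracs["te_fraction"].to_numpy(), seed=cfg.seed)
    report = pd.DataFrame(
        {
            "subclass": fracs["subclass"],
            "te_fraction": fracs["te_fraction"],
            "posterior_high": fit.posterior_upper,
            "is_high": fit.is_high,
            "pvalue": fit.pvalues,
        }
    )
    report.to_csv(out / "te_mixture.tsv", sep="\t", index=False)
    io.write_json(
        {
            "means": fit.means,
            "sds": fit.sds,
            "weights": fit.weights,
            "n_high": int(fit.is_high.sum()),
            "collapsed": fit.collapsed,
        },
        out / "te_report.json",
    )
    orth_path = out / "orthology.tsv"
    outputs = [out / "te_mixture.tsv", out / "te_report.json"]
    if orth_path.exists():
        params = {"min_fraction": 0.5, **cfg.te}
        records = pd.read_csv(orth_path, sep="\t")
        te_conservation.classify_orthology(records, **params).to_csv(
            out / "orthology_classified.tsv", sep="\t", index=False
        )
        outputs.append(out / "orthology_classified.tsv")
    _manifest(cfg, "te", cfg.te, [frac_path], outputs)
    return outputs


def _stage_loss(cfg: PipelineConfig) -> list:
    out = cfg.out
    cat, Xc, subclasses, cat_path = _read_catalogue(cfg)
    params = {"mode": "vector", "reduction": "mean", **cfg.loss}
    y_true = _pseudobulk(Xc, subclasses)  # cell types x bins (peaks)
    w = seqmodel_loss.covariance_weights(y_true, mode=params["mode"])
    y_pred = np.maximum(y_true.astype(float), 0.5)  # strictly positive predictions
    loss = seqmodel_loss.weighted_poisson_loss(y_true, y_pred, w, reduction=params["reduction"])
    io.write_json(
        {"loss": loss, "weights_mean": float(np.mean(w)), "weights_min": float(np.min(w)),
         "weights_max": float(np.max(w)), "n_types": y_true.shape[0]},
        out / "loss_report.json",
    )
    _manifest(cfg, "loss", params, [cat_path], [out / "loss_report.json"])
    return [out / "loss_report.json"]


STAGES = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "peaks": _stage_peaks,
    "modules": _stage_modules,
    "links": _stage_links,
    "grn": _stage_grn,
    "te": _stage_te,
    "loss": _stage_loss,
}


def run_stage(name: str, cfg: PipelineConfig) -> list:
    """Run one pipeline stage; returns the list of files it wrote."""
    if name not in STAGES:
        raise KeyError(f"unknown stage {name!r}; available: {sorted(STAGES)}")
    cfg.out.mkdir(parents=True, exist_ok=True)
    with open(cfg.out / "config.json", "w") as fh:
        json.dump(dataclasses.asdict(cfg), fh, indent=2)
    return STAGES[name](cfg)
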