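"""Synthetic atlas generator.

Emits every input the pipeline consumes -- a cell-by-peak binary
accessibility matrix, subclass-by-gene expression, Tn5 insertion fragment
streams, per-cluster summit calls, TE annotations and a signed regulatory
network -- together with the planted ground truth needed to score recovery.

The generative model mirrors the statistical structure the analysis
assumes rather than the sequencing process itself:

- Each peak belongs to exactly one cis-regulatory module; subclasses are
  partitioned across modules.  A cell is accessible at a peak with
  probability ``foreground_rate`` when its subclass belongs to the peak's
  module and ``background_rate`` otherwise (per-cell Bernoulli draws).
- Gene expression is Poisson with a log-scale mean sharing a latent
  subclass-level factor with the linked peak's accessibility pattern,
  giving a tunable target Pearson correlation (``link_effect``).
- Fragments are pairs of Tn5 cut sites drawn from a mixture of a uniform
  genomic background and windows of +/-150 bp around TSSs, so the planted
  TSS enrichment equals the mixture's density ratio.
- Regulatory-network expression follows a linear structural model
  x = Bx + eps with a signed acyclic weight matrix B.

A single integer seed drives a hierarchical RNG with one child stream per
artifact, so stages can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "SimulationConfig",
    "FragmentConfig",
    "GrnConfig",
    "AtlasTruth",
    "make_atlas",
    "make_fragments",
    "make_grn_truth",
    "make_summit_calls",
    "make_te_fractions",
    "stream_rng",
]

# fixed child-stream ids so artifacts can be regenerated independently
_STREAMS = {
    "atlas": 11,
    "expression": 23,
    "fragments": 37,
    "grn": 53,
    "te": 71,
    "summits": 89,
}

TE_FAMILIES = ("L1", "L2", "B2_SINE", "MIR", "ERVK", "MaLR")
TE_SUPERFAMILY = {
    "L1": "LINE",
    "L2": "LINE",
    "B2_SINE": "SINE",
    "MIR": "SINE",
    "ERVK": "LTR",
    "MaLR": "LTR",
}


def stream_rng(seed: int, stream: str) -> np.random.Generator:
    """Child RNG for one named artifact stream of a root seed."""
    if stream not in _STREAMS:
        raise KeyError(f"unknown RNG stream {stream!r}")
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],)))


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic atlas.

    Defaults are scaled so that downstream FDR calibration is meaningful
    while the whole pipeline still runs in minutes: 40 subclasses of 500
    cells, 5,000 peaks in 8 modules, 1,000 genes with 300 planted
    enhancer-gene links at a target correlation of 0.8.  Accessibility
    rates (0.02 background vs 0.30 foreground) match the sparse per-cell
    detection typical of snATAC-seq.
    """

    n_subclasses: int = 40
    n_cells_per_subclass: int = 500
    n_peaks: int = 5000
    n_genes: int = 1000
    n_modules: int = 8
    background_rate: float = 0.02
    foreground_rate: float = 0.30
    n_links: int = 300
    link_effect: float = 0.8
    # per-peak accessibility heterogeneity (s.d. of a logit-scale jitter on
    # the module base rates): real cCREs show graded, element-specific
    # accessibility, not a flat module profile, and enhancer-gene linking
    # relies on that peak-specific structure
    rate_jitter_sd: float = 1.5
    expr_mean: float = 200.0
    expr_log_sd: float = 0.7
    te_fraction_means: tuple[float, float] = (0.18, 0.30)
    te_fraction_sd: float = 0.02
    te_peak_fraction: float = 0.25
    highte_fraction: float = 0.25
    # genome layout: evenly spaced summits over a few contigs
    n_chroms: int = 4
    peak_spacing: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.background_rate < self.foreground_rate <= 1.0):
            raise ValueError("need 0 <= background_rate < foreground_rate <= 1")
        for name in ("n_subclasses", "n_cells_per_subclass", "n_peaks", "n_genes", "n_modules"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_modules > self.n_subclasses:
            raise ValueError("n_modules cannot exceed n_subclasses")
        if not (-1.0 <= self.link_effect <= 1.0):
            raise ValueError("link_effect must be in [-1, 1]")
        if self.n_links > self.n_genes:
            raise ValueError("n_links cannot exceed n_genes")


@dataclass
class AtlasTruth:
    """Planted ground truth for the synthetic atlas."""

    module_of_peak: np.ndarray  # (n_peaks,) module id per peak
    module_of_subclass: np.ndarray  # (n_subclasses,) module id per subclass
    subclass_of_cell: np.ndarray  # (n_cells,) subclass id per cell
    rate_matrix: np.ndarray  # (n_peaks, n_subclasses) Bernoulli rates
    planted_links: pd.DataFrame  # columns: peak, gene, effect
    te_label_of_peak: np.ndarray  # (n_peaks,) family name or ""
    highte_subclasses: set[int]
    grn_edges: pd.DataFrame  # columns: regulator, target, sign, weight
    peaks: pd.DataFrame  # columns: chrom, start, end, summit, peak_id
    genes: pd.DataFrame  # columns: gene, chrom, tss, strand, promoter_peak

    def __post_init__(self) -> None:
        if self.rate_matrix.min() < 0 or self.rate_matrix.max() > 1:
            raise ValueError("rate_matrix entries must lie in [0, 1]")
        if len(self.module_of_peak) != self.rate_matrix.shape[0]:
            raise ValueError("module_of_peak / rate_matrix shape mismatch")
        if len(self.planted_links):
            if self.planted_links["peak"].max() >= self.rate_matrix.shape[0]:
                raise ValueError("planted link references missing peak")
        if len(self.grn_edges):
            if (self.grn_edges["regulator"] == self.grn_edges["target"]).any():
                raise ValueError("grn_edges contain a self-loop")


def _peak_layout(config: SimulationConfig) -> pd.DataFrame:
    """Place 501-bp peaks at evenly spaced summits over a few contigs."""
    per_chrom = int(np.ceil(config.n_peaks / config.n_chroms))
    chroms, summits = [], []
    for c in range(config.n_chroms):
        n = min(per_chrom, config.n_peaks - c * per_chrom)
        if n <= 0:
            break
        chroms.extend([f"chr{c + 1}"] * n)
        summits.extend(5000 + config.peak_spacing * np.arange(n))
    summits = np.asarray(summits)
    return pd.DataFrame(
        {
            "chrom": chroms,
            "start": summits - 250,
            "end": summits + 251,
            "summit": summits,
            "peak_id": [f"peak{i}" for i in range(len(summits))],
        }
    )


def make_atlas(
    config: SimulationConfig,
) -> tuple[sp.csr_matrix, pd.DataFrame, AtlasTruth]:
    """Generate the synthetic atlas.

    Returns
    -------
    X : sparse cell-by-peak binary matrix (csr, int8)
    expression : subclass-by-gene count DataFrame
    truth : :class:`AtlasTruth`
    """
    rng = stream_rng(config.seed, "atlas")
    n_cells = config.n_subclasses * config.n_cells_per_subclass

    # module structure: balanced assignment, randomly permuted
    module_of_peak = rng.permutation(np.arange(config.n_peaks) % config.n_modules)
    module_of_subclass = rng.permutation(np.arange(config.n_subclasses) % config.n_modules)
    fg = module_of_peak[:, None] == module_of_subclass[None, :]
    base = np.where(fg, config.foreground_rate, config.background_rate)
    if config.rate_jitter_sd > 0 and 0 < base.min() and base.max() < 1:
        logit = np.log(base / (1.0 - base))
        logit += rng.normal(0.0, config.rate_jitter_sd, size=base.shape)
        rate_matrix = 1.0 / (1.0 + np.exp(-logit))
    else:
        rate_matrix = base.astype(float)

    subclass_of_cell = np.repeat(np.arange(config.n_subclasses), config.n_cells_per_subclass)

    blocks = []
    for s in range(config.n_subclasses):
        draws = rng.random((config.n_cells_per_subclass, config.n_peaks)) < rate_matrix[:, s]
        blocks.append(sp.csr_matrix(draws, dtype=np.int8))
    X = sp.vstack(blocks, format="csr")

    peaks = _peak_layout(config)

    # genes: TSS placed at the summit of a "promoter" peak
    rng_expr = stream_rng(config.seed, "expression")
    promoter_peaks = rng_expr.choice(config.n_peaks, size=config.n_genes, replace=False)
    genes = pd.DataFrame(
        {
            "gene": [f"gene{g}" for g in range(config.n_genes)],
            "chrom": peaks["chrom"].to_numpy()[promoter_peaks],
            "tss": peaks["summit"].to_numpy()[promoter_peaks],
            "strand": np.where(np.arange(config.n_genes) % 2 == 0, "+", "-"),
            "promoter_peak": promoter_peaks,
        }
    )

    # planted enhancer-gene links: a distal peak within the pairing window
    # of the gene's promoter peak, coupled at link_effect
    linked_genes = rng_expr.choice(config.n_genes, size=config.n_links, replace=False)
    link_peaks = np.empty(config.n_links, dtype=int)
    promoter_set = set(promoter_peaks.tolist())
    for k, g in enumerate(linked_genes):
        anchor = promoter_peaks[g]
        lo, hi = max(0, anchor - 40), min(config.n_peaks - 1, anchor + 40)
        candidates = [
            j
            for j in range(lo, hi + 1)
            if j != anchor
            and j not in promoter_set
            and peaks["chrom"].iat[j] == peaks["chrom"].iat[anchor]
            and abs(int(peaks["summit"].iat[j]) - int(peaks["summit"].iat[anchor])) <= 500_000
        ]
        link_peaks[k] = rng_expr.choice(candidates)
    planted_links = pd.DataFrame(
        {"peak": link_peaks, "gene": linked_genes, "effect": config.link_effect}
    )

    # expression: latent subclass factor shared with the linked peak
    z = np.zeros((config.n_subclasses, config.n_genes))
    eps = rng_expr.standard_normal((config.n_subclasses, config.n_genes))
    latent = eps.copy()
    for k in range(config.n_links):
        p, g = link_peaks[k], linked_genes[k]
        # couple to the log accessibility pattern: linking downstream
        # correlates log-normalized signals, so the planted correlation is
        # realized on the scale at which it is measured
        pattern = np.log(np.maximum(rate_matrix[p, :], 1e-6))
        sd = pattern.std()
        zp = (pattern - pattern.mean()) / sd if sd > 0 else np.zeros_like(pattern)
        z[:, g] = zp
        latent[:, g] = config.link_effect * zp + np.sqrt(
            max(0.0, 1.0 - config.link_effect**2)
        ) * eps[:, g]
    log_mu = (
        np.log(config.expr_mean) + config.expr_log_sd * latent - 0.5 * config.expr_log_sd**2
    )
    counts = rng_expr.poisson(np.exp(log_mu))
    expression = pd.DataFrame(
        counts,
        index=[f"subclass{s}" for s in range(config.n_subclasses)],
        columns=genes["gene"].tolist(),
    )

    # TE labels and highTE subclasses
    rng_te = stream_rng(config.seed, "te")
    te_label = np.array([""] * config.n_peaks, dtype=object)
    n_te = int(round(config.te_peak_fraction * config.n_peaks))
    which = rng_te.choice(config.n_peaks, size=n_te, replace=False)
    te_label[which] = rng_te.choice(TE_FAMILIES, size=n_te)
    n_high = max(1, int(round(config.highte_fraction * config.n_subclasses)))
    highte = set(rng_te.choice(config.n_subclasses, size=n_high, replace=False).tolist())

    grn_truth, _ = make_grn_truth(GrnConfig(seed=config.seed, n_cells=50))

    truth = AtlasTruth(
        module_of_peak=module_of_peak,
        module_of_subclass=module_of_subclass,
        subclass_of_cell=subclass_of_cell,
        rate_matrix=rate_matrix,
        planted_links=planted_links,
        te_label_of_peak=te_label,
        highte_subclasses=highte,
        grn_edges=grn_truth.edges[["regulator", "target", "sign", "weight"]].copy(),
        peaks=peaks,
        genes=genes,
    )
    return X, expression, truth


# ---------------------------------------------------------------------------
# fragments


@dataclass
class FragmentConfig:
    """Conditions for the fragment-stream generator.

    ``enrichment`` is the planted density ratio between the +/-150-bp TSS
    windows and the genomic background; a flat stream has enrichment 1.
    Per-barcode fragment counts default to a lognormal centred near 3,000,
    matching typical post-filter nuclei.
    """

    n_barcodes: int = 200
    contig: str = "chr1"
    contig_length: int = 2_000_000
    n_tss: int = 40
    enrichment: float = 15.0
    fragments_per_barcode: int | np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.enrichment < 1.0:
            raise ValueError("enrichment must be >= 1")
        if self.n_tss < 1:
            raise ValueError("need at least one TSS")


def make_fragments(
    config: FragmentConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate Tn5 fragment records with a planted TSS enrichment.

    Each fragment is a pair of cut sites drawn independently from a
    mixture of the uniform background and +/-150-bp TSS windows; the
    mixture weight is chosen so the site density inside the windows is
    ``enrichment`` times the flank density.  Sites are sorted per barcode
    and paired consecutively into fragments, so both fragment ends follow
    the planted profile.

    Returns (fragments, tss, barcode_truth); fragments has BED-style
    0-based half-open coordinates (chrom, start, end, barcode, count).
    """
    rng = stream_rng(config.seed, "fragments")
    margin = 10_000
    tss_pos = np.linspace(
        margin, config.contig_length - margin, config.n_tss
    ).astype(int)
    tss = pd.DataFrame(
        {
            "chrom": config.contig,
            "pos": tss_pos,
            "strand": np.where(np.arange(config.n_tss) % 2 == 0, "+", "-"),
        }
    )

    if config.fragments_per_barcode is None:
        n_frag = np.maximum(
            1, rng.lognormal(mean=np.log(3000), sigma=0.5, size=config.n_barcodes)
        ).astype(int)
    else:
        n_frag = np.broadcast_to(
            np.asarray(config.fragments_per_barcode, dtype=int), (config.n_barcodes,)
        ).copy()

    window = 150
    window_len = 2 * window + 1
    total_window = window_len * config.n_tss
    f = config.enrichment
    # density ratio (bg + tss component)/bg == f
    p_tss = (f - 1.0) * total_window / ((f - 1.0) * total_window + config.contig_length)

    rows = []
    for b in range(config.n_barcodes):
        if n_frag[b] == 0:
            continue
        n_sites = 2 * n_frag[b]
        from_tss = rng.random(n_sites) < p_tss
        sites = rng.integers(0, config.contig_length, size=n_sites)
        n_t = int(from_tss.sum())
        if n_t:
            which = rng.integers(0, config.n_tss, size=n_t)
            sites[from_tss] = tss_pos[which] + rng.integers(-window, window + 1, size=n_t)
        sites = np.sort(np.clip(sites, 0, config.contig_length - 1))
        starts = sites[0::2]
        ends = np.maximum(sites[1::2], starts + 1)
        rows.append(
            pd.DataFrame(
                {
                    "chrom": config.contig,
                    "start": starts,
                    # end is exclusive; the second cut site sits at end-1
                    "end": ends + 1,
                    "barcode": f"BC{b:05d}",
                    "count": 1,
                }
            )
        )
    fragments = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["chrom", "start", "end", "barcode", "count"])
    )
    barcode_truth = pd.DataFrame(
        {
            "barcode": [f"BC{b:05d}" for b in range(config.n_barcodes)],
            "n_fragments": n_frag,
            "target_tsse": config.enrichment,
        }
    )
    barcode_truth = barcode_truth[barcode_truth["n_fragments"] > 0].reset_index(drop=True)
    return fragments, tss, barcode_truth


# ---------------------------------------------------------------------------
# regulatory network truth


@dataclass
class GrnConfig:
    """Conditions for the linear structural-model expression generator."""

    n_tfs: int = 20
    n_targets: int = 200
    n_cells: int = 500
    parents_per_target: int = 3
    tf_parent_prob: float = 0.4
    weight_range: tuple[float, float] = (0.5, 1.5)
    positive_prob: float = 0.65
    noise_sd: float = 0.3
    driver_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.parents_per_target > self.n_tfs:
            raise ValueError("parents_per_target cannot exceed n_tfs")
        if self.noise_sd <= 0 or self.driver_sd <= 0:
            raise ValueError("noise scales must be positive")


@dataclass
class SignedNetworkTruth:
    """Planted signed regulatory network: edge list plus weight matrix B."""

    edges: pd.DataFrame  # regulator, target, sign, weight
    B: np.ndarray  # B[i, j]: coefficient of gene j in gene i's equation
    node_names: list[str]


def make_grn_truth(
    config: GrnConfig, B: np.ndarray | None = None
) -> tuple[SignedNetworkTruth, pd.DataFrame]:
    """Signed acyclic network truth and cell-by-gene expression.

    Expression follows x = Bx + eps per cell; exogenous nodes (no
    regulators) receive noise s.d. ``driver_sd`` and regulated nodes
    ``noise_sd``, so a strong single edge yields a near-deterministic
    target.  A supplied ``B`` with spectral radius >= 1 is rejected.
    """
    rng = stream_rng(config.seed, "grn")
    p = config.n_tfs + config.n_targets
    names = [f"tf{i}" for i in range(config.n_tfs)] + [
        f"gene{i}" for i in range(config.n_targets)
    ]
    if B is None:
        B = np.zeros((p, p))
        lo, hi = config.weight_range
        for i in range(1, config.n_tfs):  # TF->TF edges only forward: acyclic
            if rng.random() < config.tf_parent_prob:
                j = int(rng.integers(0, i))
                w = rng.uniform(lo, hi) * (1 if rng.random() < config.positive_prob else -1)
                B[i, j] = w
        for t in range(config.n_targets):
            i = config.n_tfs + t
            parents = rng.choice(config.n_tfs, size=config.parents_per_target, replace=False)
            signs = np.where(
                rng.random(config.parents_per_target) < config.positive_prob, 1.0, -1.0
            )
            B[i, parents] = rng.uniform(lo, hi, size=config.parents_per_target) * signs
    else:
        B = np.asarray(B, dtype=float)
        if B.shape != (p, p):
            raise ValueError("B shape does not match n_tfs + n_targets")
    if np.any(np.diag(B) != 0):
        raise ValueError("B must have a zero diagonal (no self-loops)")
    radius = np.max(np.abs(np.linalg.eigvals(B)))
    if radius >= 1.0:
        raise ValueError(f"spectral radius of B is {radius:.3f} >= 1; system unstable")

    has_parent = (B != 0).any(axis=1)
    scale = np.where(has_parent, config.noise_sd, config.driver_sd)
    eps = rng.standard_normal((config.n_cells, p)) * scale
    expr = np.linalg.solve(np.eye(p) - B, eps.T).T
    expression = pd.DataFrame(expr, columns=names)

    ii, jj = np.nonzero(B)
    edges = pd.DataFrame(
        {
            "regulator": [names[j] for j in jj],
            "target": [names[i] for i in ii],
            "sign": np.sign(B[ii, jj]).astype(int),
            "weight": B[ii, jj],
        }
    )
    return SignedNetworkTruth(edges=edges, B=B, node_names=names), expression


# ---------------------------------------------------------------------------
# summit calls and TE fractions


def make_summit_calls(
    truth: AtlasTruth,
    config: SimulationConfig,
    n_noise: int = 50,
    jitter: int = 20,
    dropout: float = 0.02,
) -> dict[int, dict[str, pd.DataFrame]]:
    """Per-subclass summit calls emulating a peak caller's five call sets.

    For each subclass the pooled set contains every peak truly accessible
    there (foreground rate) plus ``n_noise`` spurious summits that appear
    in no replicate; replicates carry the true summits with positional
    jitter and a small per-replicate dropout; pseudoreplicates carry them
    without dropout, mirroring their role of rescuing depth-limited calls.
    """
    rng = stream_rng(config.seed, "summits")
    chrom_of_peak = truth.peaks["chrom"].to_numpy()
    summit_of_peak = truth.peaks["summit"].to_numpy()
    calls: dict[int, dict[str, pd.DataFrame]] = {}
    fg_mask = truth.module_of_peak[:, None] == truth.module_of_subclass[None, :]
    for s in range(truth.rate_matrix.shape[1]):
        true_idx = np.nonzero(fg_mask[:, s])[0]
        scores = rng.lognormal(mean=np.log(50), sigma=0.4, size=len(true_idx))
        pooled = pd.DataFrame(
            {
                "chrom": chrom_of_peak[true_idx],
                "summit": summit_of_peak[true_idx],
                "score": scores,
            }
        )
        noise_pos = rng.integers(0, summit_of_peak.max(), size=n_noise)
        noise = pd.DataFrame(
            {
                "chrom": rng.choice(np.unique(chrom_of_peak), size=n_noise),
                "summit": noise_pos,
                "score": rng.lognormal(mean=np.log(5), sigma=0.3, size=n_noise),
            }
        )
        sets = {"pooled": pd.concat([pooled, noise], ignore_index=True)}
        for name, drop in (
            ("rep1", dropout),
            ("rep2", dropout),
            ("pseudo1", 0.0),
            ("pseudo2", 0.0),
        ):
            keep = rng.random(len(true_idx)) >= drop
            sets[name] = pd.DataFrame(
                {
                    "chrom": chrom_of_peak[true_idx[keep]],
                    "summit": summit_of_peak[true_idx[keep]]
                    + rng.integers(-jitter, jitter + 1, size=int(keep.sum())),
                    "score": scores[keep],
                }
            )
        calls[s] = sets
    return calls


def make_te_fractions(
    config: SimulationConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Bimodal per-subclass TE-overlap fractions.

    Returns (fractions, is_high) where fractions are Gaussian draws around
    ``te_fraction_means`` with s.d. ``te_fraction_sd`` and ``is_high``
    marks subclasses drawn from the upper component.
    """
    rng = stream_rng(config.seed, "te")
    n_high = max(1, int(round(config.highte_fraction * config.n_subclasses)))
    is_high = np.zeros(config.n_subclasses, dtype=bool)
    is_high[rng.choice(config.n_subclasses, size=n_high, replace=False)] = True
    mu = np.where(is_high, config.te_fraction_means[1], config.te_fraction_means[0])
    fractions = np.clip(rng.normal(mu, config.te_fraction_sd), 0.0, 1.0)
    return fractions, is_high
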