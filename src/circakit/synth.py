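"""Seeded synthetic-data generators.

Every generator returns both the data object and a truth record that
fully determines regeneration; all randomness flows from an explicit
seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .network import InteractionNetwork
from .signature import ExpressionStudy
from .timeseries import LuminescenceTrace


@dataclass(frozen=True)
class TraceGenParams:
    """Damped-cosine luciferase trace on a decaying baseline."""

    tau_h: float = 24.0
    amplitude: float = 0.4
    phase_h: float = 16.0
    damping_per_h: float = 0.005
    baseline: float = 1000.0
    baseline_decay_per_h: float = 0.01
    noise_sd_rel: float = 0.02
    duration_h: float = 120.0
    sampling_per_h: float = 6.0
    mode: str = "strong"
    seed: int = 0

    def __post_init__(self):
        if self.tau_h <= 0:
            raise ValueError("tau_h must be positive")
        if self.noise_sd_rel < 0:
            raise ValueError("noise SD must be >= 0")
        if self.mode not in ("strong", "weak"):
            raise ValueError("mode must be 'strong' or 'weak'")
        if self.mode == "weak" and not (self.amplitude <= 0.1 or self.damping_per_h >= 0.05):
            raise ValueError("weak mode requires amplitude <= 0.1 or damping >= 0.05/h")


WEAK_DEFAULTS = dict(amplitude=0.05, damping_per_h=0.06, mode="weak")


def gen_luminescence(params: TraceGenParams) -> tuple[LuminescenceTrace, dict]:
    """y(t) = B0 e^(-beta t) (1 + A e^(-lambda t) cos(2 pi (t-phi)/tau)) + noise."""
    rng = np.random.default_rng(params.seed)
    t = np.arange(0.0, params.duration_h + 1e-9, 1.0 / params.sampling_per_h)
    base = params.baseline * np.exp(-params.baseline_decay_per_h * t)
    osc = 1.0 + params.amplitude * np.exp(-params.damping_per_h * t) * np.cos(
        2 * np.pi * (t - params.phase_h) / params.tau_h
    )
    y = base * osc
    if params.noise_sd_rel > 0:
        y = y + rng.normal(0.0, params.noise_sd_rel * base)
    y = np.maximum(y, 1e-9)
    truth = asdict(params)
    trace = LuminescenceTrace(t, y, {"generator": "gen_luminescence", "truth": truth})
    return trace, truth


@dataclass(frozen=True)
class ExprGenParams:
    """Two-phenotype expression study with planted discriminative genes.

    Gene variances follow a scaled inverse-chi-square prior
    s0^2 d0 / chi2_{d0}; planted genes carry a phenotype mean shift of
    ``effect_sd`` gene SDs; the two timepoints of a line share a
    line-level random effect.
    """

    n_genes: int = 2000
    lines_per_phenotype: int = 3
    n_planted: int = 0
    effect_sd: float = 0.0
    d0: float = 20.0
    s0_sq: float = 0.05
    line_effect_sd: float = 0.1  # in units of each gene's residual SD
    baseline_mean: float = 7.0
    seed: int = 0

    def __post_init__(self):
        if self.n_planted >= self.n_genes:
            raise ValueError("planted gene count must be < total genes")
        if self.effect_sd < 0:
            raise ValueError("effect size must be >= 0")


def gen_expression(params: ExprGenParams) -> tuple[ExpressionStudy, list]:
    rng = np.random.default_rng(params.seed)
    G = params.n_genes
    genes = [f"G{i:05d}" for i in range(G)]
    variances = params.s0_sq * params.d0 / rng.chisquare(params.d0, size=G)
    sd = np.sqrt(variances)
    base = params.baseline_mean + rng.normal(0, 1, size=G)
    planted = sorted(rng.choice(G, size=params.n_planted, replace=False)) if params.n_planted else []

    rows_ann = []
    cols = {}
    for pheno in ("strong", "weak"):
        for li in range(params.lines_per_phenotype):
            line = f"{pheno[0].upper()}L{li}"
            line_effect = rng.normal(0, params.line_effect_sd * sd)
            for tp in (0, 48):
                sample = f"{line}_t{tp}"
                shift = np.zeros(G)
                if params.n_planted:
                    sign = 1.0 if pheno == "strong" else -1.0
                    shift[planted] = sign * params.effect_sd * sd[planted]
                noise = rng.normal(0, sd)
                cols[sample] = base + shift + line_effect + noise
                rows_ann.append((sample, line, pheno, tp))
    values = pd.DataFrame(cols, index=genes)
    ann = pd.DataFrame(rows_ann, columns=["sample", "cell_line", "phenotype", "timepoint"])
    study = ExpressionStudy(values, ann)
    return study, [genes[i] for i in planted]


def gen_test_line(
    params: ExprGenParams, phenotype: str, planted: list, seed: int,
    cell_line: str = "TESTL",
) -> pd.DataFrame:
    """Draw a held-out cell line (2 replicates) from one phenotype's generator.

    Reuses the study's gene-level prior via the same base seed so the
    planted shifts line up with ``planted``.
    """
    base_rng = np.random.default_rng(params.seed)
    G = params.n_genes
    variances = params.s0_sq * params.d0 / base_rng.chisquare(params.d0, size=G)
    sd = np.sqrt(variances)
    base = params.baseline_mean + base_rng.normal(0, 1, size=G)
    genes = [f"G{i:05d}" for i in range(G)]
    idx = [genes.index(g) for g in planted]

    rng = np.random.default_rng(seed)
    line_effect = rng.normal(0, params.line_effect_sd * sd)
    shift = np.zeros(G)
    sign = 1.0 if phenotype == "strong" else -1.0
    shift[idx] = sign * params.effect_sd * sd[idx]
    cols = {}
    for tp in (0, 48):
        cols[f"{cell_line}_t{tp}"] = base + shift + line_effect + rng.normal(0, sd)
    return pd.DataFrame(cols, index=genes)


@dataclass(frozen=True)
class NetGenParams:
    """Citation-biased interaction universe with planted enrichment."""

    n_genes: int = 500
    citation_mu: float = 3.0
    citation_sigma: float = 1.2
    base_edge_scale: float = 0.02
    query_size: int = 45
    target_size: int = 60
    enrichment: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 100:
            raise ValueError("n_genes must be >= 100")
        if self.enrichment < 1:
            raise ValueError("enrichment factor must be >= 1")


def gen_network(params: NetGenParams) -> tuple[InteractionNetwork, dict, dict]:
    """Random graph with edge probability ~ normalized citation product.

    Edges between the planted query and target sets get their probability
    multiplied by the enrichment factor. Returns (network, citations,
    truth).
    """
    rng = np.random.default_rng(params.seed)
    N = params.n_genes
    genes = [f"N{i:04d}" for i in range(N)]
    citations = np.rint(np.random.default_rng(params.seed + 1).lognormal(
        params.citation_mu, params.citation_sigma, size=N)).astype(int)
    w = (citations + 1) / (citations + 1).mean()
    perm = rng.permutation(N)
    query = set(perm[: params.query_size])
    target = set(perm[params.query_size: params.query_size + params.target_size])

    p_base = params.base_edge_scale
    exp_degree = p_base * w.mean() * N
    if exp_degree > N / 2:
        raise ValueError("expected degree exceeds N/2; lower base_edge_scale")

    g = nx.Graph()
    g.add_nodes_from(genes)
    iu, ju = np.triu_indices(N, k=1)
    p = p_base * w[iu] * w[ju]
    cross = (np.isin(iu, list(query)) & np.isin(ju, list(target))) | (
        np.isin(ju, list(query)) & np.isin(iu, list(target))
    )
    p = np.where(cross, p * params.enrichment, p)
    p = np.clip(p, 0, 1)
    draws = rng.random(p.size) < p
    for a, b in zip(iu[draws], ju[draws]):
        g.add_edge(genes[a], genes[b])
    for i, n in enumerate(genes):
        shell = "core" if i in target else ("other")
        g.nodes[n]["shell"] = shell

    cit_table = {genes[i]: int(citations[i]) for i in range(N)}
    truth = {
        "query": sorted(genes[i] for i in query),
        "target": sorted(genes[i] for i in target),
        "expected_cross_edges": float(np.sum(p[cross])),
        "params": asdict(params),
    }
    return InteractionNetwork(g), cit_table, truth


def gen_ct_table(
    genes=("PER2", "CRY1"),
    timepoints=tuple(range(24, 48, 3)),
    tau_h: float = 24.0,
    mod_depth_ct: float = 1.5,
    peak_h: float = 30.0,
    noise_sd_ct: float = 0.05,
    reference_gene: str = "GAPDH",
    samples=("CTRL", "RAS"),
    seed: int = 0,
) -> pd.DataFrame:
    """qPCR CT table with cosine-modulated targets and a flat reference.

    Lower CT means higher expression, so the modulation enters with a
    negative sign peaking at ``peak_h``.
    """
    if reference_gene in genes:
        raise ValueError("reference gene must not be among the target genes")
    rng = np.random.default_rng(seed)
    rows = []
    for sample in samples:
        for tp in timepoints:
            rows.append((sample, tp, reference_gene, 20.0 + rng.normal(0, noise_sd_ct)))
            for gene in genes:
                ct = 26.0 - mod_depth_ct * np.cos(2 * np.pi * (tp - peak_h) / tau_h)
                rows.append((sample, tp, gene, ct + rng.normal(0, noise_sd_ct)))
    return pd.DataFrame(rows, columns=["sample", "timepoint", "gene", "ct"])
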