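"""Readers/writers for the package's text formats plus run configuration.

Formats: two-column trace CSV/TSV, genes x samples expression TSV with an
annotation sidecar, GMT gene sets, tab-delimited edge lists, two-column
citation counts, SIF export, JSON result bundles. Gene symbols are
uppercased on ingest and passed through a small alias table
(e.g. ARNTL -> BMAL1).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .network import norm_symbol
from .signature import ExpressionStudy
from .timeseries import LuminescenceTrace

log = logging.getLogger("circakit")


class SchemaError(ValueError):
    pass


def _read_delim(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python")
    return df


def read_table(path, schema: dict) -> pd.DataFrame:
    """Read a delimited table and validate/coerce against ``schema``.

    ``schema`` maps required column names to dtypes (or None to skip
    coercion). Column order is irrelevant; the header is mandatory.
    """
    df = _read_delim(path)
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    for col, dtype in schema.items():
        if dtype is None:
            continue
        try:
            df[col] = df[col].astype(dtype)
        except (TypeError, ValueError) as exc:
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()].tolist()[:5]
            raise SchemaError(f"{path}: column {col!r} not {dtype} (rows {bad})") from exc
    log.info("read %s: %d rows, sha256 %s", path, len(df), file_checksum(path))
    return df


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        h.update(fh.read())
    return h.hexdigest()[:12]


# --- traces ---------------------------------------------------------------

def read_trace(path) -> LuminescenceTrace:
    df = read_table(path, {"time_h": float, "value": float})
    meta = {c: df[c].iloc[0] for c in df.columns if c not in ("time_h", "value")}
    return LuminescenceTrace(df["time_h"].to_numpy(), df["value"].to_numpy(), meta)


def write_trace(trace: LuminescenceTrace, path):
    df = pd.DataFrame({"time_h": trace.time_h, "value": trace.value})
    for key in ("detrended", "smoothed"):
        if key in trace.meta:
            df[key] = trace.meta[key]
    df.to_csv(path, index=False)


# --- expression -----------------------------------------------------------

def read_expression_study(expr_path, ann_path) -> ExpressionStudy:
    values = pd.read_csv(expr_path, sep="\t", index_col=0)
    values.index = [norm_symbol(g) for g in values.index]
    ann = read_table(ann_path, {"sample": str, "cell_line": str,
                                "phenotype": str, "timepoint": None})
    return ExpressionStudy(values, ann)


def write_expression_study(study: ExpressionStudy, expr_path, ann_path):
    study.values.to_csv(expr_path, sep="\t")
    study.annotations.to_csv(ann_path, sep="\t", index=False)


# --- gene sets ------------------------------------------------------------

def read_gmt(path_or_text, aliases: dict | None = None) -> dict:
    """GMT: name <tab> description <tab> gene1 <tab> gene2 ... per line."""
    if isinstance(path_or_text, str) and "\n" in path_or_text:
        lines = path_or_text.splitlines()
    else:
        with open(path_or_text) as fh:
            lines = fh.read().splitlines()
    sets = {}
    for line in lines:
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise SchemaError(f"GMT line with fewer than 3 fields: {line[:60]!r}")
        genes = [apply_alias(norm_symbol(g), aliases) for g in parts[2:] if g.strip()]
        if not genes:
            raise SchemaError(f"empty gene set {parts[0]!r}")
        sets[parts[0]] = genes
    return sets


def write_gmt(sets: dict, path, descriptions: dict | None = None):
    with open(path, "w") as fh:
        for name, genes in sets.items():
            desc = (descriptions or {}).get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def write_gene_list(genes, path):
    with open(path, "w") as fh:
        fh.write("\n".join(genes) + "\n")


# --- networks -------------------------------------------------------------

EDGE_SCHEMA = {"src": str, "dst": str}


def read_edges(path, aliases: dict | None = None) -> pd.DataFrame:
    df = read_table(path, EDGE_SCHEMA)
    for col in ("src", "dst"):
        df[col] = [apply_alias(norm_symbol(s), aliases) for s in df[col]]
    for col, default in (("type", "other"), ("source", "other"),
                         ("pubmed_ids", ""), ("confidence", 1.0)):
        if col not in df.columns:
            df[col] = default
    return df


def read_citations(path) -> dict:
    df = read_table(path, {"gene": str, "citations": int})
    return {norm_symbol(g): int(c) for g, c in zip(df["gene"], df["citations"])}


def write_citations(citations: dict, path):
    pd.DataFrame(
        {"gene": list(citations), "citations": list(citations.values())}
    ).to_csv(path, sep="\t", index=False)


def write_sif(network, path):
    g = network.graph
    with open(path, "w") as fh:
        for u, v, attrs in g.edges(data=True):
            fh.write(f"{u}\t{attrs.get('type', 'other')}\t{v}\n")


# --- packaged fixtures ----------------------------------------------------

def load_aliases() -> dict:
    text = resources.files("circakit.data").joinpath("aliases.tsv").read_text()
    out = {}
    for line in text.splitlines()[1:]:
        if line.strip():
            alias, symbol = line.split("\t")
            out[norm_symbol(alias)] = norm_symbol(symbol)
    return out


def apply_alias(symbol: str, aliases: dict | None = None) -> str:
    if aliases is None:
        return symbol
    return aliases.get(symbol, symbol)


def load_gene_catalog() -> dict:
    """The packaged named gene sets (core clock, clock/cancer related, signature)."""
    text = resources.files("circakit.data").joinpath("genesets.gmt").read_text()
    return read_gmt(text, aliases=load_aliases())


def load_shell_fixture_edges() -> pd.DataFrame:
    with resources.as_file(
        resources.files("circakit.data").joinpath("shell_fixture_edges.tsv")
    ) as p:
        return read_edges(p, aliases=load_aliases())


FIRST_SHELL_FIXTURE = (
    "AHR", "ALAS1", "AMPK", "BTRC", "CAR", "CBP", "CK2", "CREB",
    "CSNK1D", "CSNK1E", "CSNK2A1", "DBP", "DEC1", "DEC2", "E4BP4", "FBXL3",
)


# --- run configuration / pipeline ----------------------------------------

@dataclass
class RunConfig:
    """End-to-end pipeline configuration; every stochastic stage is seeded."""

    stages: list = field(default_factory=lambda: ["rhythm", "signature", "network", "model"])
    seed: int | None = None
    detrend_window_h: float = 24.0
    smooth_window_h: float = 4.0
    top_k: int = 100
    n_null_sets: int = 50
    ktt_grid: tuple = (0.4, 0.7, 1.0, 1.3, 1.6)
    rtol: float = 1e-8
    atol: float = 1e-10
    out_path: str = "results.json"

    def validate(self):
        stochastic = {"signature", "network"} & set(self.stages)
        if stochastic and self.seed is None:
            raise SchemaError(f"stages {sorted(stochastic)} require an explicit seed")
        return self

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["ktt_grid"] = list(self.ktt_grid)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


def run_pipeline(config: RunConfig) -> dict:
    """Demo end-to-end run on seeded synthetic inputs.

    Executes the requested stages in order and returns a single JSON-able
    bundle with per-stage outputs and full provenance.
    """
    from . import __version__, clockmodel, network, signature, synth, timeseries

    config.validate()
    bundle = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "version": __version__,
        "stages": {},
    }
    seed = config.seed if config.seed is not None else 0
    try:
        if "rhythm" in config.stages:
            trace, truth = synth.gen_luminescence(synth.TraceGenParams(seed=seed))
            det = timeseries.detrend_running_average(trace, config.detrend_window_h)
            fit = timeseries.fit_damped_cosine(det)
            cls = timeseries.classify_oscillator(fit)
            bundle["stages"]["rhythm"] = {
                "truth": truth, "fit": fit.to_dict(), "class": cls.label,
            }
        if "signature" in config.stages:
            study, planted = synth.gen_expression(
                synth.ExprGenParams(n_genes=1000, n_planted=20, effect_sd=2.0, seed=seed)
            )
            folds = signature.loocv_discriminative_lists(study, top_k=config.top_k)
            folds = [signature.validate_fold_by_clustering(study, f) for f in folds]
            final = signature.intersect_lists(folds)
            bundle["stages"]["signature"] = {
                "n_folds": len(folds),
                "retained": [f.excluded_cell_line for f in folds if f.retained],
                "signature_size": len(final),
                "recovered_planted": len(set(final) & set(planted)),
            }
        if "network" in config.stages:
            net, citations, truth = synth.gen_network(
                synth.NetGenParams(enrichment=3.0, seed=seed)
            )
            null = network.citation_bin_null(
                citations, truth["query"], [truth["target"]], net,
                B=config.n_null_sets, seed=seed,
            )
            bundle["stages"]["network"] = null.to_dict()
        if "model" in config.stages:
            model = clockmodel.default_model()
            taus = {}
            for ktt in config.ktt_grid:
                f = clockmodel.features_of(clockmodel.apply_bmal_scaling(model, ktt))
                taus[str(ktt)] = f.period_h
            bundle["stages"]["model"] = {"tau_by_ktt": taus}
    except Exception as exc:
        bundle["error"] = {"stage": _last_stage(bundle), "message": str(exc)}
        raise
    return bundle


def _last_stage(bundle):
    stages = list(bundle.get("stages", {}))
    return stages[-1] if stages else "(first stage)"


def write_bundle(bundle: dict, path):
    with open(path, "w") as fh:
        json.dump(bundle, fh, indent=2, sort_keys=True, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
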