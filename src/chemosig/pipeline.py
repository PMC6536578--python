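"""End-to-end orchestration: inputs -> IC50 -> signature -> cluster -> test.

A :class:`RunConfig` names exactly one source for the expression panel (a
TSV file or the simulator) and exactly one source for the drug response (a
log10(IC50) CSV, an IC50 CSV, a long-format plate CSV to estimate IC50s
from, or the simulator). :func:`run_pipeline` executes the stages in order,
writes every stage artifact plus a machine-readable JSON run report into the
output directory, and is byte-for-byte reproducible for a fixed config and
seed (no timestamps, sorted JSON keys, fixed float formatting).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, defaults, io
from .cluster import (cut_dendrogram, dichotomize_response, test_predictability,
                      ward_cluster)
from .dose_response import estimate_ic50, normalize_viability
from .exceptions import ChemosigError, PipelineError, ValidationError
from .signature import align_panel, correlate_genes, select_signature
from .synthetic import PanelSimConfig, generate_panel

__all__ = ["RunConfig", "run_pipeline", "parse_flat_config"]

_BOOL = {"true": True, "false": False, "1": True, "0": False,
         "yes": True, "no": False}


def parse_flat_config(path) -> dict:
    """Parse a flat ``key = value`` text file (``#`` comments, blank lines ok).

    Raises :class:`ValidationError` naming the offending line number on a
    malformed line.
    """
    mapping: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValidationError(
                f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, _, value = line.partition("=")
        key = key.strip()
        if not key:
            raise ValidationError(f"{path}:{lineno}: empty key")
        mapping[key] = value.strip()
    return mapping


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    outdir: str = "chemosig_out"
    seed: int = 0
    drug: str = "simdrug"
    # panel source: a TSV path or the simulator
    panel: str | None = None
    simulate: bool = False
    # response source: one of these paths, or the simulator
    response: str | None = None
    ic50: str | None = None
    plates: str | None = None
    # simulator conditions
    n_cell_lines: int = 47
    n_null_genes: int = 2000
    n_pos_genes: int = 20
    n_neg_genes: int = 20
    target_r: float = 0.7
    response_mean: float = 1.5
    response_sd: float = 0.4
    # analysis parameters
    ic50_method: str = "interpolation"
    k_signature: int = defaults.K_SIGNATURE
    r_min: float = defaults.R_MIN
    k_clusters: int = defaults.K_CLUSTERS
    tie_rule: str = defaults.MEDIAN_TIE_RULE
    mc_reps: int | None = None

    def __post_init__(self) -> None:
        panel_sources = [self.panel is not None, self.simulate]
        if sum(panel_sources) != 1:
            raise ValidationError(
                "panel: exactly one source required (panel=<tsv> or simulate=true)")
        resp_sources = [self.response is not None, self.ic50 is not None,
                        self.plates is not None, self.simulate]
        if sum(resp_sources) != 1:
            raise ValidationError(
                "response: exactly one source required "
                "(response=, ic50=, plates= or simulate=true)")
        if self.k_signature <= 0:
            raise ValidationError(f"k_signature: must be > 0, got {self.k_signature}")
        if not (0.0 <= self.r_min < 1.0):
            raise ValidationError(f"r_min: must be in [0, 1), got {self.r_min}")
        if self.k_clusters < 1:
            raise ValidationError(f"k_clusters: must be >= 1, got {self.k_clusters}")
        if self.ic50_method not in ("interpolation", "four_parameter_logistic"):
            raise ValidationError(f"ic50_method: unknown method {self.ic50_method!r}")

    _COERCE = {
        "seed": int, "n_cell_lines": int, "n_null_genes": int,
        "n_pos_genes": int, "n_neg_genes": int, "k_signature": int,
        "k_clusters": int, "mc_reps": int,
        "target_r": float, "response_mean": float, "response_sd": float,
        "r_min": float,
        "simulate": lambda v: _BOOL[str(v).strip().lower()],
    }

    @classmethod
    def from_mapping(cls, mapping: dict, **overrides) -> "RunConfig":
        merged = {**mapping, **{k: v for k, v in overrides.items()
                                if v is not None}}
        kwargs = {}
        for key, value in merged.items():
            if key not in cls.__dataclass_fields__:
                raise ValidationError(f"unknown config key {key!r}")
            if isinstance(value, str) and key in cls._COERCE:
                try:
                    value = cls._COERCE[key](value)
                except (ValueError, KeyError) as exc:
                    raise ValidationError(
                        f"{key}: cannot parse {value!r}") from exc
            kwargs[key] = value
        return cls(**kwargs)

    def canonical(self) -> dict:
        d = asdict(self)
        d.pop("outdir")  # the output location does not change the science
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.canonical(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _ic50_table_from_plates(path, method: str) -> pd.DataFrame:
    datasets = io.read_plates_csv(path)
    rows = []
    for cell, ds in datasets.items():
        est = estimate_ic50(normalize_viability(ds), method=method)
        rows.append((cell, est.value, est.censor, est.method))
    return pd.DataFrame(rows, columns=["cell_line", "ic50_um", "censor",
                                       "method"]).set_index("cell_line")


def _stage(report: dict, name: str):
    """Context manager wrapping a stage: records errors with the stage name."""
    class _Ctx:
        def __enter__(self):
            return report["stages"].setdefault(name, {})

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(name, str(exc)) from exc
            return False

    return _Ctx()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the run report (also written as JSON)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config": config.canonical(),
        "config_hash": config.config_hash(),
        "stages": {},
        "warnings": [],
    }
    truth = None

    with _stage(report, "inputs") as summary:
        if config.simulate:
            sim = PanelSimConfig(
                n_cell_lines=config.n_cell_lines,
                n_null_genes=config.n_null_genes,
                n_pos_genes=config.n_pos_genes,
                n_neg_genes=config.n_neg_genes,
                target_r=config.target_r,
                response_mean=config.response_mean,
                response_sd=config.response_sd,
                seed=config.seed, drug=config.drug)
            panel, response, truth = generate_panel(sim)
            io.write_panel_tsv(panel, outdir / "panel.tsv")
            io.write_response_csv(response, outdir / "response.csv")
            io.write_ground_truth_tsv(truth, list(panel.index),
                                      outdir / "ground_truth.tsv")
            summary["source"] = "simulated"
        else:
            panel = io.read_panel_tsv(config.panel)
            summary["source"] = "files"
            if config.response:
                response = io.read_response_csv(config.response, drug=config.drug)
            elif config.ic50 or config.plates:
                if config.plates:
                    table = _ic50_table_from_plates(config.plates,
                                                    config.ic50_method)
                    io.write_ic50_csv(table, outdir / "ic50_table.csv")
                    censored = table["censor"] != "none"
                    if censored.any():
                        report["warnings"].append(
                            f"{int(censored.sum())} cell line(s) with censored "
                            "IC50 excluded from the response")
                    table = table[~censored]
                    report["stages"]["ic50"] = {
                        "n_cell_lines": int(len(table)),
                        "n_censored": int(censored.sum()),
                        "method": config.ic50_method,
                    }
                else:
                    table = io.read_ic50_csv(config.ic50)
                response = pd.Series(
                    np.log10(table["ic50_um"].to_numpy(float)),
                    index=table.index.astype(str), name=config.drug)
        summary["n_genes"] = int(panel.shape[0])
        summary["n_cell_lines_panel"] = int(panel.shape[1])
        summary["n_cell_lines_response"] = int(response.size)
    if "ic50" not in report["stages"]:
        report["stages"]["ic50"] = {
            "skipped": "response provided directly; no plate data to fit"}

    with _stage(report, "signature") as summary:
        panel, response = align_panel(panel, response)
        records = correlate_genes(panel, response)
        records.reset_index().to_csv(outdir / "correlations.tsv", sep="\t",
                                     index=False, float_format=io.FLOAT_FORMAT)
        selection = select_signature(records, k=config.k_signature,
                                     r_min=config.r_min)
        selection.to_frame().to_csv(outdir / "signature.tsv", sep="\t",
                                    index=False, float_format=io.FLOAT_FORMAT)
        report["warnings"].extend(selection.warnings)
        summary["n_genes_correlated"] = int(len(records))
        summary["n_genes_excluded"] = records.attrs["n_excluded"]
        summary["n_positive"] = int(len(selection.top_positive))
        summary["n_negative"] = int(len(selection.top_negative))
        if truth is not None:
            planted = truth.planted_pos | truth.planted_neg
            if planted:
                hits = planted & set(selection.gene_ids)
                summary["planted_recovery"] = round(len(hits) / len(planted), 4)

    signature_genes = selection.gene_ids
    if not signature_genes:
        reason = f"no genes pass |r| >= {config.r_min}; nothing to cluster on"
        report["stages"]["cluster"] = {"skipped": reason}
        report["stages"]["predict"] = {"skipped": reason}
        io.write_json(report, outdir / "report.json")
        return report

    with _stage(report, "cluster") as summary:
        sub = panel.loc[signature_genes]
        dend = ward_cluster(sub)
        (outdir / "dendrogram.nwk").write_text(dend.to_newick() + "\n")
        partition = cut_dendrogram(dend, k=min(config.k_clusters,
                                               dend.n_leaves))
        io.write_partition_csv(partition, outdir / "partition.csv")
        # clustered-image-map matrix: z-scored, columns in dendrogram leaf order
        mu = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=1)
        cim = sub.sub(mu, axis=0).div(sd.replace(0.0, np.nan), axis=0)
        cim = cim.loc[:, dend.leaf_order()]
        cim.to_csv(outdir / "cim_matrix.tsv", sep="\t",
                   index_label="gene_id", float_format=io.FLOAT_FORMAT)
        summary["n_signature_genes"] = int(sub.shape[0])
        summary["k"] = partition.k
        summary["cluster_sizes"] = partition.sizes

    with _stage(report, "predict") as summary:
        dichotomy = dichotomize_response(response, tie_rule=config.tie_rule)
        result = test_predictability(partition, dichotomy,
                                     mc_reps=config.mc_reps, seed=config.seed)
        payload = {
            "median_cutoff": dichotomy.median_cutoff,
            "class_counts": dichotomy.counts,
            "observed": result.table.to_numpy().tolist(),
            "expected": result.expected.round(6).to_numpy().tolist(),
            "statistic": round(result.statistic, 6),
            "df": result.df,
            "p_value": result.p_value,
            "min_expected": round(result.min_expected, 6),
            "mc_p_value": result.mc_p_value,
            "mc_reps": result.mc_reps,
        }
        io.write_json(payload, outdir / "predictability.json")
        summary.update(payload)

    io.write_json(report, outdir / "report.json")
    return report
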