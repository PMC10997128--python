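"""End-to-end orchestration: simulate/load -> index -> tables -> fit -> CCR.

The pipeline mirrors the analysis order of the study it emulates: build the
composite undernutrition index from the z-scores, describe outcome and
covariate frequencies, screen covariates with chi-square tests, tabulate the
joint 2x2 distribution with its odds ratio, fit the bivariate logistic model
with the global odds-ratio association, and report the correct
classification rate.  Each stage writes a JSON artifact (and optionally a
text rendering); a manifest records the config hash, seed and library
versions so runs are reproducible byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import anthro, diagnostics, io as nio, synthdata, tables
from . import bivlogit

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger("nutrilink")

_STAGES = (
    "composite_index",
    "frequencies",
    "chi_square",
    "joint_table",
    "bivariate_fit",
    "ccr",
)


@dataclass
class PipelineConfig:
    """Everything one run needs; exactly one of input_csv / synthetic."""

    output_dir: str | Path = "nutrilink_out"
    input_csv: str | Path | None = None
    synthetic: synthdata.SyntheticConfig | dict | None = None
    column_mapping: dict[str, str] = field(default_factory=dict)
    covariates: list[str] | None = None
    reference_levels: dict[str, str] = field(default_factory=dict)
    weight_column: str | None = "weight"
    composite_cutoff: float = -2.0
    standardize_composite: bool = False
    hemoglobin_cutoff: float = 11.0
    undernutrition_source: str = "column"   # "column" | "composite"
    ccr_rule: str = "argmax_joint"
    rounding_digits: int = 3
    seed: int = 0
    formats: tuple[str, ...] = ("json", "text")

    def __post_init__(self):
        if (self.input_csv is None) == (self.synthetic is None):
            raise ValueError("exactly one of input_csv / synthetic must be set")
        if isinstance(self.synthetic, dict):
            merged = dict(self.synthetic)
            merged.setdefault("seed", self.seed)
            self.synthetic = synthdata.SyntheticConfig.from_dict(merged)
        if self.undernutrition_source not in ("column", "composite"):
            raise ValueError("undernutrition_source must be 'column' or 'composite'")

    def to_dict(self) -> dict:
        d = {
            "output_dir": str(self.output_dir),
            "input_csv": None if self.input_csv is None else str(self.input_csv),
            "synthetic": None if self.synthetic is None else self.synthetic.to_dict(),
            "column_mapping": dict(self.column_mapping),
            "covariates": self.covariates,
            "reference_levels": dict(self.reference_levels),
            "weight_column": self.weight_column,
            "composite_cutoff": self.composite_cutoff,
            "standardize_composite": self.standardize_composite,
            "hemoglobin_cutoff": self.hemoglobin_cutoff,
            "undernutrition_source": self.undernutrition_source,
            "ccr_rule": self.ccr_rule,
            "rounding_digits": self.rounding_digits,
            "seed": self.seed,
            "formats": list(self.formats),
        }
        return d


def _fixed(obj, digits: int = 10):
    """Round all floats for stable JSON rendering."""
    if isinstance(obj, float):
        return round(obj, digits)
    if isinstance(obj, dict):
        return {k: _fixed(v, digits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_fixed(v, digits) for v in obj]
    if isinstance(obj, np.generic):
        return _fixed(obj.item(), digits)
    if isinstance(obj, np.ndarray):
        return _fixed(obj.tolist(), digits)
    return obj


def _write_json(path: Path, payload) -> None:
    path.write_text(json.dumps(_fixed(payload), indent=2, sort_keys=True) + "\n")


def _write_text(path: Path, text: str) -> None:
    path.write_text(text.rstrip() + "\n")


def _load_dataset(config: PipelineConfig) -> pd.DataFrame:
    if config.input_csv is not None:
        data = nio.read_child_table(
            config.input_csv,
            mapping=config.column_mapping,
            hemoglobin_cutoff=config.hemoglobin_cutoff,
        )
    else:
        data = synthdata.generate_dataset(config.synthetic)
    covs = config.covariates
    if covs is None:
        reserved = set(nio.NUMERIC_COLUMNS) | set(nio.BINARY_COLUMNS)
        covs = [c for c in data.columns if c not in reserved]
        config.covariates = covs
    missing = [c for c in covs if c not in data.columns]
    for col in ("haz", "waz", "whz"):
        if col not in data.columns:
            missing.append(col)
    if missing:
        raise ValueError(f"input is missing required columns: {missing}")
    return data


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage, writing artifacts under ``config.output_dir``.

    Returns a summary dict (the manifest payload).  On a stage failure the
    error is logged with the stage name and re-raised; artifacts from
    earlier stages are retained.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    as_text = "text" in config.formats

    stage = "load"
    manifest_stages = {}
    try:
        data = _load_dataset(config)
        manifest_stages["load"] = {"rows_out": int(len(data))}

        # 1. composite index -------------------------------------------------
        stage = "composite_index"
        weights = data[config.weight_column].to_numpy() if config.weight_column in data else None
        index_result = anthro.build_composite_index(
            data,
            cutoff=config.composite_cutoff,
            standardize=config.standardize_composite,
            weights=weights,
        )
        data = data.loc[index_result.composite_scores.index].copy()
        data["composite"] = index_result.composite_scores
        if weights is not None:
            weights = data[config.weight_column].to_numpy()
        if config.undernutrition_source == "composite" or "undernutrition" not in data:
            data["undernutrition"] = index_result.undernutrition
        _write_json(outdir / "composite_index.json", index_result.report())
        if as_text:
            ev = index_result.eigenvalues
            pr = index_result.proportion_explained
            lines = ["Composite undernutrition index (PCA of HAZ/WAZ/WHZ)", ""]
            lines.append("eigenvalue  proportion  cumulative")
            cum = 0.0
            for lam, p in zip(ev, pr):
                cum += p
                lines.append(f"{lam:10.3f}  {p:10.3f}  {cum:10.3f}")
            scree = [
                f"PC{k + 1} " + "#" * int(round(40 * p))
                for k, p in enumerate(pr)
            ]
            lines += ["", "PC1 loadings: "
                      + ", ".join(f"{v:.3f}" for v in index_result.loadings[:, 0]),
                      "", *scree]
            _write_text(outdir / "composite_index.txt", "\n".join(lines))
        manifest_stages[stage] = {
            "rows_in": index_result.n_used + index_result.n_dropped,
            "rows_out": index_result.n_used,
        }

        # 2. frequency tables ------------------------------------------------
        stage = "frequencies"
        freq_vars = ["anemia", "undernutrition"] + list(config.covariates)
        freq = tables.frequency_report(data, freq_vars, weights=weights)
        _write_json(outdir / "frequencies.json", freq.to_dict(orient="records"))
        if as_text:
            _write_text(outdir / "frequencies.txt", freq.to_string(index=False))
        manifest_stages[stage] = {"rows_out": int(len(freq))}

        # 3. chi-square screen -----------------------------------------------
        stage = "chi_square"
        screen = tables.chi_square_screen(data, list(config.covariates))
        _write_json(outdir / "chi_square.json", screen.to_dict(orient="records"))
        if as_text:
            shown = screen.drop(columns=["counts", "levels"])
            _write_text(outdir / "chi_square.txt", shown.to_string(index=False))
        manifest_stages[stage] = {"rows_out": int(len(screen))}

        # 4. joint/marginal table ----------------------------------------------
        stage = "joint_table"
        y = data[["anemia", "undernutrition"]]
        joint = tables.joint_marginal_table(
            y, weights=weights, rounding_digits=config.rounding_digits
        )
        _write_json(outdir / "joint_table.json", joint.to_dict())
        if as_text:
            txt = joint.to_frame().to_string(index=False)
            txt += (
                f"\n\nOR from counts: {joint.or_from_counts:.3f}"
                f"\nOR from {joint.rounding_digits}-dp rounded probabilities: "
                f"{joint.or_from_rounded_probs:.3f}"
            )
            _write_text(outdir / "joint_table.txt", txt)
        manifest_stages[stage] = {"rows_out": 1}

        # 5. bivariate fit ------------------------------------------------------
        stage = "bivariate_fit"
        design = bivlogit.DesignMatrix.from_dataframe(
            data,
            covariates=list(config.covariates),
            reference_levels=config.reference_levels,
            weight_column=config.weight_column if config.weight_column in data else None,
        )
        fit_result = bivlogit.fit(design, y)
        fit_payload = {
            "converged": fit_result.converged,
            "n_iter": fit_result.n_iter,
            "loglik": fit_result.loglik,
            "log_psi": fit_result.log_psi,
            "psi": fit_result.psi,
            "n_obs": fit_result.n_obs,
            "reference_levels": fit_result.reference_levels,
            "variance_note": fit_result.variance_note,
            "aor_table": None
            if fit_result.aor_table is None
            else fit_result.aor_table.to_dict(orient="records"),
        }
        _write_json(outdir / "bivariate_fit.json", fit_payload)
        if as_text and fit_result.aor_table is not None:
            tbl = fit_result.aor_table.copy()
            for c in ("estimate", "se", "aor", "ci_low", "ci_high"):
                tbl[c] = tbl[c].round(3)
            tbl["p_value"] = tbl["p_value"].round(4)
            txt = tbl.to_string(index=False)
            txt += (
                f"\n\nassociation odds ratio psi = {fit_result.psi:.3f}"
                f"  (log psi = {fit_result.log_psi:.4f})"
                f"\nlog-likelihood = {fit_result.loglik:.4f}"
                f"  iterations = {fit_result.n_iter}"
                f"\nnote: {fit_result.variance_note}"
            )
            _write_text(outdir / "bivariate_fit.txt", txt)
        manifest_stages[stage] = {
            "converged": bool(fit_result.converged),
            "n_iter": int(fit_result.n_iter),
        }

        # 6. CCR -------------------------------------------------------------------
        stage = "ccr"
        ccr = diagnostics.correct_classification_rate(
            fit_result, design, y, rule=config.ccr_rule
        )
        _write_json(outdir / "ccr.json", ccr.to_dict())
        if as_text:
            _write_text(
                outdir / "ccr.txt",
                (
                    f"rule: {ccr.rule}\n"
                    f"joint CCR: {ccr.joint_ccr:.3f}\n"
                    f"marginal CCR (anemia): {ccr.marginal_ccr_anemia:.3f}\n"
                    f"marginal CCR (undernutrition): "
                    f"{ccr.marginal_ccr_undernutrition:.3f}"
                ),
            )
        manifest_stages[stage] = {"joint_ccr": round(float(ccr.joint_ccr), 6)}
    except Exception:
        logger.exception("pipeline stage %r failed", stage)
        raise

    config_json = json.dumps(_fixed(config.to_dict()), sort_keys=True)
    manifest = {
        "config": json.loads(config_json),
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "seed": config.seed if config.synthetic is None else config.synthetic.seed,
        "stages": manifest_stages,
        "versions": {
            "nutrilink": _package_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "artifacts": sorted(p.name for p in outdir.iterdir() if p.is_file()),
    }
    _write_json(outdir / "manifest.json", manifest)
    return manifest


def _package_version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("nutrilink")
    except PackageNotFoundError:
        return "unknown"
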