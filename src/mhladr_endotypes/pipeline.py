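"""End-to-end orchestration: preprocess -> cluster -> trend -> outcomes -> report.

The pipeline consumes the long trajectory CSV (patient_id, cohort, day,
mhla_dr) and optionally an outcomes CSV (patient_id, time, event), runs
every analysis stage, and writes one JSON manifest holding every estimate
and the seeds that produced them. Each stochastic stage draws its seed
deterministically from the run seed plus a stage tag.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._version import __version__
from .kml import TrajectoryCohort, kmeans_longitudinal, mean_assignment_probability, name_endotypes
from .outcomes import CompetingRiskData, outcome_report
from .preprocess import clean_trajectories
from .trend import fit_trend, predict_band

__all__ = ["RunConfig", "run_pipeline", "stage_seed"]

logger = logging.getLogger(__name__)


def stage_seed(seed: int, tag: str) -> int:
    """Deterministic per-stage seed from the run seed and a stage tag."""
    return (seed * 1000003 + zlib.crc32(tag.encode())) % (2**31 - 1)


@dataclass
class RunConfig:
    """Pipeline parameters (all JSON round-trippable)."""

    seed: int = 0
    k: int = 4
    n_restarts: int = 1000
    k_fence: float = 2.0
    band_times: list = field(default_factory=lambda: [1 + 0.25 * i for i in range(25)])
    band_draws: int = 2000
    horizon: float = 28.0
    reference: str = "Non-improvers"

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and (np.isnan(obj) or np.isinf(obj)):
        return None
    return obj


def run_pipeline(
    trajectories: pd.DataFrame,
    outcomes: pd.DataFrame | None = None,
    config: RunConfig | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Run the full analysis and return (and optionally write) the manifest."""
    config = config or RunConfig()

    # preprocess
    clean = clean_trajectories(trajectories, k_fence=config.k_fence)
    cohort = TrajectoryCohort.from_long(clean.data)

    # cluster
    partition = kmeans_longitudinal(
        cohort, k=config.k, n_restarts=config.n_restarts, seed=stage_seed(config.seed, "cluster")
    )
    centers_abc = clean.transform.inverse(partition.centers)
    partition.names = name_endotypes(centers_abc)
    endotype_of = np.array([partition.names[c] for c in partition.assignment])

    manifest = {
        "version": __version__,
        "config": asdict(config),
        "preprocess": {
            "lambda": clean.transform.lambda_,
            "fences": [clean.report.lower_fence, clean.report.upper_fence],
            "n_flagged": len(clean.report.flagged),
            "dropped_patients": clean.dropped_patients,
        },
        "partition": {
            "k": partition.k,
            "ch": partition.ch,
            "names": partition.names,
            "centers_transformed": partition.centers,
            "centers_abc": centers_abc,
            "mean_assignment_probability": mean_assignment_probability(partition),
            "sizes": {partition.names[c]: int((partition.assignment == c).sum()) for c in range(partition.k)},
            "best_restart_seed": partition.best_restart_seed,
            "assignment": {str(p): partition.names[c] for p, c in zip(cohort.patients, partition.assignment)},
        },
    }

    # trend
    trend_data = clean.data.merge(
        pd.DataFrame({"patient_id": cohort.patients, "endotype": endotype_of}), on="patient_id"
    )
    fit = fit_trend(trend_data)
    bands = {}
    for g in fit.coefficients if fit.converged else ():
        band = predict_band(
            fit,
            g,
            config.band_times,
            n_draws=config.band_draws,
            seed=stage_seed(config.seed, f"band:{g}"),
            inverse=clean.transform.inverse,
        )
        bands[g] = {"times": band.times, "mean": band.mean, "lo95": band.lo95, "hi95": band.hi95}
    manifest["trend"] = {
        "coefficients": {g: list(v) for g, v in fit.coefficients.items()},
        "var_intercept": fit.var_intercept,
        "var_slope": fit.var_slope,
        "cov_intercept_slope": fit.cov_intercept_slope,
        "var_resid": fit.var_resid,
        "converged": fit.converged,
        "bands": bands,
        "band_note": "fixed-effects-uncertainty bands, not prediction intervals",
    }

    # outcomes
    if outcomes is not None:
        assign = pd.Series(endotype_of, index=cohort.patients, name="endotype")
        oc = outcomes.copy()
        if "endotype" not in oc.columns:
            oc = oc.merge(assign.rename_axis("patient_id").reset_index(), on="patient_id", how="inner")
        data = CompetingRiskData(oc[["patient_id", "time", "event", "endotype"]])
        report = outcome_report(data, reference=config.reference)
        manifest["outcomes"] = {
            "cif_at_horizon": {
                e: {g: cif.at(config.horizon) for g, cif in by_group.items()}
                for e, by_group in report["cif"].items()
            },
            "last_at_risk": {
                e: {g: cif.last_at_risk_value for g, cif in by_group.items()}
                for e, by_group in report["cif"].items()
            },
            "fine_gray": report["shr_table"].to_dict(orient="records"),
        }
    else:
        logger.warning("no outcomes table supplied; outcomes stage skipped")
        manifest["outcomes"] = None

    manifest = _jsonify(manifest)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        pd.DataFrame(
            {
                "patient_id": cohort.patients,
                "cluster": partition.assignment,
                "endotype": endotype_of,
                "p_assign": partition.posterior[np.arange(cohort.n_patients), partition.assignment],
            }
        ).to_csv(outdir / "partition.csv", index=False)
    return manifest
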