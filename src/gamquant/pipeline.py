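"""End-to-end orchestration: simulate -> quantify -> filter -> survive -> expression.

A single :class:`RunConfig` drives every stage; all randomness is derived
from per-stage seeds computed from the one top-level seed, so an
identical config produces a byte-identical report.  Each stage records
its status in the report; a failed stage marks downstream stages as
skipped and the run as failed (nonzero exit at the CLI).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .errors import ConfigurationError, GamquantError
from . import cohort as cs
from . import expression as es
from . import ihc
from . import synthetic as syn

__all__ = ["RunConfig", "run_pipeline", "write_report"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (YAML-serializable)."""

    out_dir: str = "gamquant_run"
    seed: int = 0
    simulate: bool = True
    input_dir: str | None = None  # directory of spot images when simulate=False

    # image quantification
    n_spots: int = 20
    spot_fraction_min: float = 0.05
    spot_fraction_max: float = 0.50
    haze_kind: str = "constant"
    haze_start: float = 0.1
    haze_end: float | None = None
    threshold_method: str = "li"
    histogram_bins: int = 256

    # cohort
    n_patients: int = 120
    log_hazard_ratio: float = -0.5
    censoring_rate: float = 0.2
    cores_per_patient: int = 1
    necrosis_cutoff: float = 0.30
    split: str = "median"
    min_arm_fraction: float = 0.10
    alpha: float = 0.05

    # expression
    n_genes: int = 300
    n_case_samples: int = 6
    n_ref_samples: int = 3
    planted_deg_count: int = 10
    planted_log2fc: float = 3.0
    expression_noise_sd: float = 0.2
    deg_threshold: float = 2.0
    pfp_permutations: int = 200

    def __post_init__(self) -> None:
        if self.threshold_method not in ("li", "kapur"):
            raise ConfigurationError("threshold_method must be li|kapur")
        if self.split not in ("median", "best"):
            raise ConfigurationError("split must be median|best")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must lie in (0, 1)")
        if not 0 <= self.min_arm_fraction < 0.5:
            raise ConfigurationError("min_arm_fraction must lie in [0, 0.5)")

    # -- stage seeds: fixed offsets from the master seed, kept below 2**31
    def stage_seed(self, stage: str) -> int:
        offsets = {"spots": 1, "cohort": 2, "expression": 3, "pfp": 4}
        return int((self.seed * 10 + offsets[stage]) % (2**31 - 1))

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _stage_quantify(config: RunConfig) -> dict:
    haze = syn.HazeProfile(config.haze_kind, config.haze_start, config.haze_end)
    rows = []
    if config.simulate:
        rng = np.random.default_rng(config.stage_seed("spots"))
        for i in range(config.n_spots):
            frac = float(
                rng.uniform(config.spot_fraction_min, config.spot_fraction_max)
            )
            spot = syn.generate_spot(
                syn.SpotSpec(
                    positive_fraction=frac,
                    haze=haze,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
            )
            res = ihc.quantify_spot(
                spot.image, bins=config.histogram_bins, method=config.threshold_method
            )
            row = res.as_row(f"spot_{i:04d}")
            row["true_fraction"] = spot.true_fraction
            rows.append(row)
    else:
        import imageio.v3 as iio

        in_dir = Path(config.input_dir or "")
        if not in_dir.is_dir():
            raise GamquantError(f"input directory not found: {in_dir}")
        paths = sorted(
            p for p in in_dir.iterdir() if p.suffix.lower() in (".png", ".tif", ".tiff")
            and "mask" not in p.stem
        )
        if not paths:
            raise GamquantError(f"no spot images in {in_dir}")
        for p in paths:
            res = ihc.quantify_spot(
                np.asarray(iio.imread(p)),
                bins=config.histogram_bins,
                method=config.threshold_method,
            )
            rows.append(res.as_row(p.stem))
    out = {"spots": rows, "n_spots": len(rows)}
    ratios = [r["ratio"] for r in rows]
    out["mean_ratio"] = float(np.mean(ratios))
    if rows and "true_fraction" in rows[0]:
        errs = [abs(r["ratio"] - r["true_fraction"]) for r in rows]
        out["mean_abs_error_vs_truth"] = float(np.mean(errs))
    return out


def _stage_survival(config: RunConfig) -> dict:
    spec = syn.CohortSpec(
        n_patients=config.n_patients,
        log_hazard_ratio_high_vs_low=config.log_hazard_ratio,
        censoring_rate=config.censoring_rate,
        cores_per_patient=config.cores_per_patient,
        seed=config.stage_seed("cohort"),
    )
    table = syn.generate_cohort(spec)
    filtered = cs.exclude_necrotic(
        cs.first_core_select(table), max_necrosis=config.necrosis_cutoff
    )
    splitter = cs.median_split if config.split == "median" else cs.best_split
    comp = splitter(filtered)
    result = comp.to_dict()
    result["n_after_filters"] = int(len(filtered))
    result["n_excluded_necrotic"] = filtered.attrs.get("n_excluded_necrotic", 0)
    result["significance"] = cs.significance_stars(comp.logrank.p_value)
    if comp.scan is not None:
        result["scan"] = comp.scan.to_dict(orient="records")
    return result


def _stage_expression(config: RunConfig) -> dict:
    rng = np.random.default_rng(config.stage_seed("expression"))
    genes = [f"g{i + 1:05d}" for i in range(config.n_genes)]
    chosen = rng.choice(config.n_genes, size=config.planted_deg_count, replace=False)
    signs = rng.choice([-1.0, 1.0], size=config.planted_deg_count)
    planted = {
        genes[int(i)]: float(s * config.planted_log2fc)
        for i, s in zip(chosen, signs)
    }
    spec = syn.ExpressionSpec(
        n_genes=config.n_genes,
        n_case_samples=config.n_case_samples,
        n_ref_samples=config.n_ref_samples,
        planted=planted,
        noise_sd=config.expression_noise_sd,
        seed=config.stage_seed("expression"),
    )
    matrix = syn.generate_expression(spec)
    degs = es.deg_filter(matrix, threshold=config.deg_threshold)
    pfp = es.rank_product_pfp(
        matrix,
        n_permutations=config.pfp_permutations,
        seed=config.stage_seed("pfp"),
    )
    hits = degs[degs["passed"]]
    planted_set = set(planted)
    return {
        "n_genes": config.n_genes,
        "planted": sorted(planted_set),
        "n_deg": int(len(hits)),
        "deg_recovered_planted": int(len(planted_set & set(hits.index))),
        "n_pfp_lt_0.01": int(
            ((pfp["pfp_up"] < 0.01) | (pfp["pfp_down"] < 0.01)).sum()
        ),
    }


_STAGES = [
    ("quantify", _stage_quantify),
    ("survival", _stage_survival),
    ("expression", _stage_expression),
]


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return (and write) the run report.

    The report echoes the config and per-stage seeds; identical config
    implies an identical report.  On stage failure the remaining stages
    are skipped and ``report['status']`` is ``'failed'``.
    """
    report: dict = {
        "gamquant_version": __version__,
        "config": asdict(config),
        "stage_seeds": {s: config.stage_seed(s) for s in ("spots", "cohort", "expression", "pfp")},
        "stages": {},
        "status": "ok",
    }
    failed = False
    for name, fn in _STAGES:
        if failed:
            report["stages"][name] = {"status": "skipped"}
            continue
        try:
            result = fn(config)
            report["stages"][name] = {"status": "ok", "result": result}
        except Exception as exc:  # noqa: BLE001 - reported, not swallowed
            report["stages"][name] = {
                "status": "failed",
                "error": f"{type(exc).__name__}: {exc}",
            }
            failed = True
    report["status"] = "failed" if failed else "ok"
    write_report(report, Path(config.out_dir) / "report.json")
    return report


def write_report(report: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(report, sort_keys=True, indent=2, default=float))
    return path
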