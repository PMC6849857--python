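"""Ground-truthed synthetic inputs for every pipeline stage.

Three generators mirror the data the analysis consumes, so the whole
pipeline is testable without patient material:

``generate_spot``
    An H-DAB TMA spot rendered through the Beer–Lambert forward model:
    stains are composed in optical-density space (absorbances add) and
    converted to 8-bit RGB as ``I = 255 * 10**(-OD . stain_vector)``.
    Positive cells are filled discs with Gaussian-blurred edges on top of
    a configurable background DAB haze (constant or linear gradient); the
    sharp pre-blur disc union is kept as the ground-truth positive mask,
    so the true DAB-area fraction is known exactly.

``generate_cohort``
    A per-patient, per-core marker table with exponential survival whose
    hazard is multiplied by ``exp(log_hazard_ratio)`` for patients whose
    marker lies above the dichotomization point (cohort median by
    default, or a fixed change-point), plus independent censoring.

``generate_expression``
    A log2 genes x samples matrix with Gaussian noise and a planted set
    of differentially expressed genes.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .errors import ParameterError
from .expression import ExpressionMatrix
from .ihc import HDAB, StainMatrix

__all__ = [
    "HazeProfile",
    "SpotSpec",
    "GroundTruthSpot",
    "CohortSpec",
    "ExpressionSpec",
    "generate_spot",
    "generate_cohort",
    "generate_expression",
    "save_spot",
    "save_cohort",
    "save_expression",
]


# ---------------------------------------------------------------------------
# spot generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HazeProfile:
    """Background DAB optical density over the tissue.

    ``constant``: uniform OD ``start``.  ``linear``: OD ramps from
    ``start`` at the left image edge to ``end`` at the right edge.
    """

    kind: str = "constant"
    start: float = 0.1
    end: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "linear"):
            raise ParameterError("haze kind must be 'constant' or 'linear'")
        if self.start < 0 or (self.end is not None and self.end < 0):
            raise ParameterError("haze OD must be non-negative")

    @property
    def max_od(self) -> float:
        return max(self.start, self.end if self.end is not None else self.start)

    def render(self, height: int, width: int) -> np.ndarray:
        if self.kind == "constant":
            return np.full((height, width), self.start)
        end = self.start if self.end is None else self.end
        ramp = np.linspace(self.start, end, width)
        return np.tile(ramp, (height, 1))


@dataclass(frozen=True)
class SpotSpec:
    """Parameters of one synthetic TMA spot.

    The tissue core is a disc centered in the frame
    (``tissue_radius_frac`` of the smaller image dimension); the rest is
    unstained glass.  ``positive_fraction`` is the target fraction of
    tissue area covered by DAB-positive cells.
    """

    width: int = 256
    height: int = 256
    cell_count: int = 250
    positive_fraction: float = 0.2
    dab_od_mean: float = 0.8
    dab_od_sd: float = 0.12  # cell-to-cell staining variability
    haze: HazeProfile = field(default_factory=HazeProfile)
    haze_texture_sd: float = 0.08  # spatially correlated unspecific DAB background
    haze_texture_scale: float = 3.0  # correlation length, px
    hematoxylin_od_mean: float = 0.6
    tissue_background_od: float = 0.12
    tissue_radius_frac: float = 0.45
    positive_cell_radius: tuple[int, int] = (9, 14)
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ParameterError("image dimensions must be positive")
        if not 0.0 <= self.positive_fraction <= 1.0:
            raise ParameterError("positive_fraction must lie in [0, 1]")
        if self.dab_od_mean <= self.haze.max_od:
            raise ParameterError("dab_od_mean must exceed the background haze OD")
        for name in ("dab_od_mean", "hematoxylin_od_mean", "tissue_background_od"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        if min(self.noise_sd, self.dab_od_sd, self.haze_texture_sd) < 0:
            raise ParameterError("noise/OD standard deviations must be non-negative")
        if self.cell_count < 0:
            raise ParameterError("cell_count must be non-negative")
        if not 0 < self.tissue_radius_frac <= 0.5:
            raise ParameterError("tissue_radius_frac must lie in (0, 0.5]")
        rmin, rmax = self.positive_cell_radius
        if not 1 <= rmin <= rmax:
            raise ParameterError("positive_cell_radius must satisfy 1 <= min <= max")


@dataclass
class GroundTruthSpot:
    """A rendered spot with its per-pixel ground truth.

    ``true_fraction = positive_mask.sum() / tissue_mask.sum()``; the OD
    fields (after noise, before 8-bit quantization) are kept so tests can
    verify that deconvolution recovers them.
    """

    image: np.ndarray          # H x W x 3 uint8
    positive_mask: np.ndarray  # bool, subset of tissue_mask
    tissue_mask: np.ndarray    # bool
    true_fraction: float
    dab_od: np.ndarray
    hematoxylin_od: np.ndarray
    spec: SpotSpec


def _disc_offsets(radius: int) -> tuple[np.ndarray, np.ndarray]:
    ax = np.arange(-radius, radius + 1)
    dy, dx = np.meshgrid(ax, ax, indexing="ij")
    inside = dy**2 + dx**2 <= radius**2
    return dy[inside], dx[inside]


def _stamp(mask: np.ndarray, cy: int, cx: int, radius: int) -> None:
    dy, dx = _disc_offsets(radius)
    ys = np.clip(cy + dy, 0, mask.shape[0] - 1)
    xs = np.clip(cx + dx, 0, mask.shape[1] - 1)
    mask[ys, xs] = True


def generate_spot(spec: SpotSpec) -> GroundTruthSpot:
    """Render one spot through the Beer–Lambert forward model.

    Positive-cell discs (radius drawn from ``positive_cell_radius``) are
    placed at random uncovered
    tissue pixels until the covered fraction reaches the target, so the
    realized fraction overshoots by at most one disc (< 0.5 percentage
    points at default geometry).  Absorbances compose additively in OD
    space; edges are softened with a sigma = 1 px Gaussian blur *after*
    the ground-truth mask is frozen.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    radius = spec.tissue_radius_frac * min(h, w)
    tissue = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
    tissue_idx = np.flatnonzero(tissue)
    tissue_area = tissue.sum()

    # nuclei (hematoxylin): small discs at random tissue positions
    nuclei = np.zeros((h, w), dtype=bool)
    if spec.cell_count > 0 and tissue_idx.size:
        centers = rng.choice(tissue_idx, size=spec.cell_count, replace=True)
        radii = rng.integers(2, 4, size=spec.cell_count)
        for c, r in zip(centers, radii):
            _stamp(nuclei, c // w, c % w, int(r))

    # DAB-positive cells: discs until target area fraction reached; each
    # cell carries its own stain intensity (truncated normal around
    # dab_od_mean), as real DAB uptake varies cell to cell.
    positive = np.zeros((h, w), dtype=bool)
    cell_od = np.zeros((h, w))
    od_floor = spec.haze.max_od + 0.1
    if spec.positive_fraction > 0:
        target_px = spec.positive_fraction * tissue_area
        rmin, rmax = spec.positive_cell_radius
        while (positive & tissue).sum() < target_px:
            open_idx = np.flatnonzero(tissue & ~positive)
            if open_idx.size == 0:
                break
            c = int(rng.choice(open_idx))
            r = int(rng.integers(rmin, rmax + 1))
            od = float(
                np.clip(rng.normal(spec.dab_od_mean, spec.dab_od_sd), od_floor, None)
            )
            dy, dx = _disc_offsets(r)
            ys = np.clip(c // w + dy, 0, h - 1)
            xs = np.clip(c % w + dx, 0, w - 1)
            positive[ys, xs] = True
            cell_od[ys, xs] = np.maximum(cell_od[ys, xs], od)
    positive &= tissue
    cell_od[~tissue] = 0.0
    true_fraction = float(positive.sum() / tissue_area)

    hem = gaussian_filter(
        np.where(nuclei, spec.hematoxylin_od_mean, 0.0), sigma=1.0
    )
    hem = np.maximum(hem, np.where(tissue, spec.tissue_background_od, 0.0))
    dab = gaussian_filter(cell_od, sigma=1.0)
    background = spec.haze.render(h, w)
    if spec.haze_texture_sd > 0:
        # smooth random field; gaussian_filter shrinks the variance of white
        # noise, so renormalize to unit sd before scaling
        raw = gaussian_filter(
            rng.normal(0.0, 1.0, size=(h, w)), sigma=spec.haze_texture_scale
        )
        background = background + spec.haze_texture_sd * raw / raw.std()
    dab = dab + np.where(tissue, np.clip(background, 0.0, None), 0.0)

    if spec.noise_sd > 0:
        hem = hem + rng.normal(0.0, spec.noise_sd, size=hem.shape)
        dab = dab + rng.normal(0.0, spec.noise_sd, size=dab.shape)
    hem = np.clip(hem, 0.0, None)
    dab = np.clip(dab, 0.0, None)

    od_rgb = hem[..., None] * HDAB.vectors[0] + dab[..., None] * HDAB.vectors[1]
    image = np.clip(np.rint(255.0 * 10.0 ** (-od_rgb)), 0, 255).astype(np.uint8)

    return GroundTruthSpot(
        image=image,
        positive_mask=positive,
        tissue_mask=tissue,
        true_fraction=true_fraction,
        dab_od=dab,
        hematoxylin_od=hem,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# cohort generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic survival cohort.

    Markers (% positive cells) follow a right-skewed Beta(2,5) scaled to
    [0, 100] by default.  Survival is exponential with rate
    ``baseline_hazard`` (per month), multiplied by
    ``exp(log_hazard_ratio_high_vs_low)`` for patients whose underlying
    marker exceeds ``hazard_cutpoint`` (the cohort median when None).
    Censoring: each patient is independently censored with probability
    ``censoring_rate``, uniformly before their event time.
    """

    n_patients: int = 241
    marker: str = "Iba1"
    marker_distribution: tuple = ("beta", 2.0, 5.0)
    log_hazard_ratio_high_vs_low: float = 0.0
    baseline_hazard: float = 0.046  # per month; median OS ~ 15 months
    censoring_rate: float = 0.2
    cores_per_patient: int = 1
    core_noise_sd: float = 2.0
    hazard_cutpoint: float | None = None
    regions: tuple[str, ...] = ("T",)
    necrosis_beta: tuple[float, float] = (1.0, 19.0)
    group: str = "GBM_IDH1R132H_nonmut"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ParameterError("need at least two patients")
        if not 1 <= self.cores_per_patient <= 3:
            raise ParameterError("cores_per_patient must be 1-3")
        if not 0.0 <= self.censoring_rate <= 1.0:
            raise ParameterError("censoring_rate must lie in [0, 1]")
        if self.baseline_hazard <= 0:
            raise ParameterError("baseline_hazard must be positive")
        if self.core_noise_sd < 0:
            raise ParameterError("core_noise_sd must be non-negative")
        if self.marker_distribution[0] != "beta":
            raise ParameterError("only the 'beta' marker family is implemented")


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate a cohort table (one row per patient x region x core)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    _, a, b = spec.marker_distribution
    marker = 100.0 * rng.beta(a, b, size=n)

    cut = float(np.median(marker)) if spec.hazard_cutpoint is None else spec.hazard_cutpoint
    high = marker > cut
    rate = spec.baseline_hazard * np.exp(
        spec.log_hazard_ratio_high_vs_low * high.astype(float)
    )
    event_time = rng.exponential(1.0 / rate)
    censored = rng.random(n) < spec.censoring_rate
    u = rng.uniform(0.0, 1.0, size=n)
    time = np.where(censored, np.maximum(u * event_time, 1e-6), event_time)
    event = (~censored).astype(int)

    rows = []
    for i in range(n):
        pid = f"P{i + 1:04d}"
        for region in spec.regions:
            region_marker = (
                marker[i]
                if region == spec.regions[0]
                else 100.0 * rng.beta(a, b)
            )
            for core in range(1, spec.cores_per_patient + 1):
                value = region_marker + rng.normal(0.0, spec.core_noise_sd)
                rows.append(
                    {
                        "patient_id": pid,
                        "core_index": core,
                        "marker": spec.marker,
                        "value": float(np.clip(value, 0.0, 100.0)),
                        "necrosis_fraction": float(
                            rng.beta(*spec.necrosis_beta)
                        ),
                        "region": region,
                        "group": spec.group,
                        "survival_months": float(time[i]),
                        "event": int(event[i]),
                    }
                )
    df = pd.DataFrame(rows)
    df.attrs["hazard_cutpoint"] = cut
    return df


# ---------------------------------------------------------------------------
# expression generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpressionSpec:
    """Parameters of a synthetic two-condition log2 expression matrix.

    ``planted`` maps gene ids to their true log2 fold change (case minus
    reference); other genes are null.  Mirrors a design of several case
    samples against a small (possibly single pooled) reference.
    """

    n_genes: int = 1000
    n_case_samples: int = 6
    n_ref_samples: int = 1
    planted: dict[str, float] = field(default_factory=dict)
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_case_samples < 1 or self.n_ref_samples < 1:
            raise ParameterError("need >= 1 gene and >= 1 sample per condition")
        if self.noise_sd < 0 or self.baseline_sd < 0:
            raise ParameterError("standard deviations must be non-negative")
        valid = set(self.gene_ids())
        bad = [g for g in self.planted if g not in valid]
        if bad:
            raise ParameterError(f"planted ids outside gene set: {bad[:5]}")

    def gene_ids(self) -> list[str]:
        return [f"g{i + 1:05d}" for i in range(self.n_genes)]


def generate_expression(spec: ExpressionSpec) -> ExpressionMatrix:
    """Simulate a log2 expression matrix with planted fold changes."""
    rng = np.random.default_rng(spec.seed)
    genes = spec.gene_ids()
    case_cols = [f"GAM_{i + 1}" for i in range(spec.n_case_samples)]
    ref_cols = [f"WM_ref_{i + 1}" for i in range(spec.n_ref_samples)]
    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, size=spec.n_genes)
    shift = np.array([spec.planted.get(g, 0.0) for g in genes])

    n_samples = spec.n_case_samples + spec.n_ref_samples
    noise = (
        rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, n_samples))
        if spec.noise_sd > 0
        else np.zeros((spec.n_genes, n_samples))
    )
    values = baseline[:, None] + noise
    values[:, : spec.n_case_samples] += shift[:, None]
    data = pd.DataFrame(values, index=genes, columns=case_cols + ref_cols)
    return ExpressionMatrix(data, case_samples=case_cols, reference_samples=ref_cols)


# ---------------------------------------------------------------------------
# on-disk artifacts (image + sidecar JSON provenance)
# ---------------------------------------------------------------------------

def _sidecar(path: Path, spec) -> None:
    payload = dataclasses.asdict(spec)
    path.with_suffix(".json").write_text(json.dumps(payload, indent=2, default=str))


def save_spot(spot: GroundTruthSpot, directory, stem: str, fmt: str = "png") -> Path:
    """Write the spot image, its masks and a provenance sidecar.

    Masks are 8-bit PNGs (0 = background, 255 = mask).  Returns the
    image path.
    """
    import imageio.v3 as iio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if fmt == "tiff":
        import tifffile

        img_path = directory / f"{stem}.tiff"
        tifffile.imwrite(img_path, spot.image)
    elif fmt == "png":
        img_path = directory / f"{stem}.png"
        iio.imwrite(img_path, spot.image)
    else:
        raise ParameterError("fmt must be 'png' or 'tiff'")
    for name, mask in (
        ("positive_mask", spot.positive_mask),
        ("tissue_mask", spot.tissue_mask),
    ):
        iio.imwrite(directory / f"{stem}_{name}.png", mask.astype(np.uint8) * 255)
    _sidecar(directory / stem, spot.spec)
    return img_path


def save_cohort(table: pd.DataFrame, path, spec: CohortSpec | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    if spec is not None:
        _sidecar(path, spec)
    return path


def save_expression(
    matrix: ExpressionMatrix, path, spec: ExpressionSpec | None = None
) -> Path:
    """Write the matrix CSV plus a condition-map CSV alongside it."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    matrix.data.to_csv(path, index_label="gene")
    cond = pd.DataFrame(
        {
            "sample": matrix.case_samples + matrix.reference_samples,
            "condition": ["case"] * len(matrix.case_samples)
            + ["reference"] * len(matrix.reference_samples),
        }
    )
    cond.to_csv(path.with_name(path.stem + "_conditions.csv"), index=False)
    if spec is not None:
        _sidecar(path, spec)
    return path
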