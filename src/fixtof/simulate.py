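"""Synthetic TOF traces and stained-tissue images with known ground truth.

The TOF generator is the forward model of the monitor: a single
exponential ``A*exp(-t/tau) + C`` sampled at a fixed cadence across a
handful of vertical transducer positions, with a per-position offset and
sub-nanosecond Gaussian noise.  The image generator produces a
brightfield disk of tissue whose DAB positivity decays with distance
from the tissue edge — the spatial signature of formalin diffusing in
from the periphery — rendered through inverse optical-density mixing of
hematoxylin and DAB reference colors so the stain-quantification
pipeline can be validated end to end.

Every generator is a pure function of (spec, seed) and returns its
ground truth alongside the artifact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import InvalidArgumentError
from .tof_model import TofTrace

__all__ = [
    "SyntheticTofSpec",
    "TofCohortSampler",
    "SyntheticIhcSpec",
    "simulate_tof_trace",
    "simulate_cohort",
    "simulate_ihc_image",
    "HDAB_VECTORS",
]

# Standard H-DAB color-deconvolution reference vectors (unit optical-density
# directions for hematoxylin and DAB in RGB), columns = stains.
HDAB_VECTORS = np.array(
    [
        [0.650, 0.268],
        [0.704, 0.570],
        [0.286, 0.776],
    ]
)
HDAB_VECTORS = HDAB_VECTORS / np.linalg.norm(HDAB_VECTORS, axis=0)


@dataclass(frozen=True)
class SyntheticTofSpec:
    """Forward-model parameters for one synthetic TOF trace.

    Defaults mimic a mid-size specimen: amplitude 40 ns, decay constant
    2.5 hr, offset 5 ns, 7 transducer positions read every 5 minutes with
    0.5 ns additive noise (sub-nanosecond measurement precision).
    """

    tau: float = 2.5
    amplitude: float = 40.0
    offset: float = 5.0
    noise_sd: float = 0.5
    cadence: float = 5.0  # minutes between points
    duration: float = 8.0  # hours
    n_positions: int = 7
    position_jitter_sd: float = 1.0  # ns, static between-position offsets
    calibration_tof: float = 0.0
    seed: int = 0
    sample_id: str = "synthetic"

    def __post_init__(self) -> None:
        for name in ("tau", "amplitude", "duration", "cadence"):
            if getattr(self, name) <= 0:
                raise InvalidArgumentError(f"{name} must be > 0")
        if self.noise_sd < 0 or self.position_jitter_sd < 0:
            raise InvalidArgumentError("noise parameters must be >= 0")
        if self.n_positions < 1:
            raise InvalidArgumentError("n_positions must be >= 1")


def simulate_tof_trace(spec: SyntheticTofSpec) -> TofTrace:
    """Generate one position-resolved TOF trace.

    Each reading is ``A*exp(-t/tau) + C + calibration + position offset
    + N(0, noise_sd)``; the static position offsets (N(0, position_jitter_sd),
    zero-mean across positions) model the mm-scale heterogeneity of the
    specimen along the vertical scan axis.  Ground-truth parameters are
    attached in ``trace.metadata["truth"]``.
    """
    rng = np.random.default_rng(spec.seed)
    n_t = int(round(spec.duration * 60.0 / spec.cadence)) + 1
    times = np.arange(n_t) * spec.cadence / 60.0
    positions = np.arange(spec.n_positions, dtype=float)  # mm, 1 mm apart
    clean = spec.amplitude * np.exp(-times / spec.tau) + spec.offset
    pos_offsets = rng.normal(0.0, spec.position_jitter_sd, spec.n_positions)
    pos_offsets -= pos_offsets.mean()  # jitter redistributes, not biases
    raw = (
        clean[:, None]
        + spec.calibration_tof
        + pos_offsets[None, :]
        + rng.normal(0.0, spec.noise_sd, (n_t, spec.n_positions))
    )
    return TofTrace(
        sample_id=spec.sample_id,
        times=times,
        positions=positions,
        raw_tof=raw,
        calibration_tof=spec.calibration_tof,
        metadata={
            "truth": {
                "tau": spec.tau,
                "amplitude": spec.amplitude,
                "offset": spec.offset,
            },
            "spec": spec,
        },
    )


@dataclass(frozen=True)
class TofCohortSampler:
    """Per-trace parameter distributions for a synthetic retrospective cohort.

    Decay constants are drawn Uniform(1.5, 3.5) hr — the range spanned by
    small surgical specimens across organs — with amplitudes Uniform(20, 60)
    ns and offsets Uniform(0, 10) ns.  By default each trace carries the
    instrument geometry: 7 vertical positions read with 0.5 ns precision
    each, so the spatially averaged point the monitor consumes has noise
    0.5/sqrt(7) ns.  Set ``n_positions=1`` to place the full noise directly
    on the averaged signal instead.
    """

    tau_range: tuple[float, float] = (1.5, 3.5)
    amplitude_range: tuple[float, float] = (20.0, 60.0)
    offset_range: tuple[float, float] = (0.0, 10.0)
    noise_sd: float = 0.5
    cadence: float = 5.0
    duration: float = 8.0
    n_positions: int = 7
    position_jitter_sd: float = 1.0


def simulate_cohort(
    sampler: TofCohortSampler | None = None,
    n: int = 105,
    seed: int = 42,
) -> list[TofTrace]:
    """Draw ``n`` traces with per-trace parameters from ``sampler``.

    Reproducible for a fixed seed; each trace is tagged with its true
    parameters in metadata.
    """
    if n <= 0:
        raise InvalidArgumentError("cohort size n must be > 0")
    sampler = sampler or TofCohortSampler()
    rng = np.random.default_rng(seed)
    traces = []
    for i in range(n):
        spec = SyntheticTofSpec(
            tau=float(rng.uniform(*sampler.tau_range)),
            amplitude=float(rng.uniform(*sampler.amplitude_range)),
            offset=float(rng.uniform(*sampler.offset_range)),
            noise_sd=sampler.noise_sd,
            cadence=sampler.cadence,
            duration=sampler.duration,
            n_positions=sampler.n_positions,
            position_jitter_sd=sampler.position_jitter_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
            sample_id=f"synthetic-{i:03d}",
        )
        traces.append(simulate_tof_trace(spec))
    return traces


# ---------------------------------------------------------------------------
# Synthetic IHC images
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticIhcSpec:
    """Parameters of the synthetic DAB-stained tissue disk.

    ``penetration`` is the half-decay depth of the positivity gradient:
    a cell at edge distance d is DAB-positive with probability

        p(d) = background + (edge - background) * 2**(-d / penetration)

    so positivity halves (above background) every ``penetration`` mm into
    the tissue — the suppressed-core pattern of an underfixed specimen.
    """

    tissue_radius: float = 3.0  # mm
    pixel_size: float = 0.01  # mm/px
    penetration: float = 1.0  # mm
    edge_positivity: float = 0.8
    background_positivity: float = 0.05
    cell_density: float = 400.0  # cells/mm^2 (tessellation seed density)
    cell_radius: int = 4  # px, sets tessellation region scale
    hole_spec: tuple[int, float] | None = None  # (count, radius mm)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.background_positivity <= self.edge_positivity <= 1.0:
            raise InvalidArgumentError(
                "need 0 <= background_positivity <= edge_positivity <= 1"
            )
        if self.penetration <= 0:
            raise InvalidArgumentError("penetration must be > 0")
        if self.tissue_radius <= 0 or self.pixel_size <= 0:
            raise InvalidArgumentError("tissue_radius and pixel_size must be > 0")
        if 2 * self.tissue_radius / self.pixel_size > 4096:
            raise InvalidArgumentError("image would exceed the 4096 px cap")


def _render_od(h_od: np.ndarray, d_od: np.ndarray) -> np.ndarray:
    """Inverse optical-density mixing: concentrations -> 8-bit RGB."""
    od = h_od[..., None] * HDAB_VECTORS[:, 0] + d_od[..., None] * HDAB_VECTORS[:, 1]
    rgb = 255.0 * np.power(10.0, -od)
    return np.clip(np.round(rgb), 0, 255).astype(np.uint8)


def simulate_ihc_image(spec: SyntheticIhcSpec) -> tuple[np.ndarray, dict]:
    """Render a synthetic brightfield H-DAB image of a tissue disk.

    The tissue is tessellated into cell-scale regions (nearest seed point
    of a Poisson process); each region is hematoxylin-stained and is
    DAB-positive with probability ``p(d)`` evaluated at its seed, where
    ``d`` is the seed's distance to the tissue edge.  Optional circular
    white holes model non-staining tears.

    Returns ``(rgb, truth)`` where ``truth`` holds the tissue mask, hole
    mask, analyzable mask, per-pixel positivity-probability field, the
    region label map and the per-region positive flags.
    """
    rng = np.random.default_rng(spec.seed)
    r_px = spec.tissue_radius / spec.pixel_size
    size = int(np.ceil(2 * r_px)) + 8
    yy, xx = np.mgrid[0:size, 0:size]
    cy = cx = size / 2.0
    rr = np.hypot(yy - cy, xx - cx)
    tissue = rr <= r_px

    # edge distance (mm) inside the tissue
    dist_px = ndimage.distance_transform_edt(tissue)
    d_mm = dist_px * spec.pixel_size
    p_field = spec.background_positivity + (
        spec.edge_positivity - spec.background_positivity
    ) * np.power(2.0, -d_mm / spec.penetration)
    p_field[~tissue] = 0.0

    # cell-scale tessellation: nearest-seed regions over the whole disk
    region_area_px = np.pi * spec.cell_radius**2
    n_seeds = max(16, int(tissue.sum() / region_area_px))
    seed_idx = rng.choice(np.flatnonzero(tissue), size=n_seeds, replace=False)
    seed_mask = np.zeros_like(tissue)
    seed_mask.flat[seed_idx] = True
    _, (iy, ix) = ndimage.distance_transform_edt(~seed_mask, return_indices=True)
    flat_seed_label = np.full(tissue.size, -1, dtype=np.int64)
    flat_seed_label[seed_idx] = np.arange(n_seeds)
    labels = flat_seed_label[(iy * size + ix).ravel()].reshape(tissue.shape)
    labels[~tissue] = -1

    seed_y, seed_x = np.unravel_index(seed_idx, tissue.shape)
    seed_d = d_mm[seed_y, seed_x]
    p_seed = spec.background_positivity + (
        spec.edge_positivity - spec.background_positivity
    ) * np.power(2.0, -seed_d / spec.penetration)
    positive = rng.random(n_seeds) < p_seed

    pos_px = np.zeros_like(tissue)
    inside = labels >= 0
    pos_px[inside] = positive[labels[inside]]

    h_od = np.zeros((size, size))
    d_od = np.zeros((size, size))
    h_od[tissue] = 0.45 + rng.normal(0.0, 0.02, int(tissue.sum()))
    d_od[pos_px] = 0.80 + rng.normal(0.0, 0.04, int(pos_px.sum()))

    holes = np.zeros_like(tissue)
    if spec.hole_spec is not None:
        n_holes, hole_r_mm = spec.hole_spec
        hole_r_px = hole_r_mm / spec.pixel_size
        for _ in range(int(n_holes)):
            # keep holes strictly interior so they stay enclosed by tissue
            rad = rng.uniform(0, max(r_px - 3 * hole_r_px, 0))
            ang = rng.uniform(0, 2 * np.pi)
            hy, hx = cy + rad * np.sin(ang), cx + rad * np.cos(ang)
            holes |= np.hypot(yy - hy, xx - hx) <= hole_r_px
        holes &= tissue
        h_od[holes] = 0.0
        d_od[holes] = 0.0

    rgb = _render_od(np.clip(h_od, 0, None), np.clip(d_od, 0, None))
    truth = {
        "tissue_mask": tissue,
        "hole_mask": holes,
        "analyzable_mask": tissue & ~holes,
        "positivity_probability": p_field,
        "region_labels": labels,
        "region_positive": positive,
        "spec": spec,
    }
    return rgb, truth
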