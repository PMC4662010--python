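"""Synthetic microchannel image simulator with ground truth.

Emulates the appearance of surface-deposited, restriction-digested,
fluorescently stained DNA in a microchannel: molecules are bright
curvilinear ridges along the flow (column) axis with a Gaussian transverse
intensity profile, gaps at restriction cut sites flanked by brighter cut
ends (coil relaxation), a co-deposited size standard, ~25 % inter-frame
overlap along the channel, constant background and additive Gaussian read
noise. Each fragment's total rendered intensity (before noise) equals
``adu_per_kb * size_kb``, so integrated-fluorescence sizing can be checked
against exact ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .types import Frame, StandardSpec, lambda_bsu36i

__all__ = [
    "SimulationParams",
    "TrueMolecule",
    "GroundTruth",
    "render_fragment",
    "simulate_channel",
    "write_fixture",
]


@dataclass
class SimulationParams:
    """Knobs of the synthetic channel.

    Defaults model the standard acquisition: 1040 x 1392 frames at
    100 nm/pixel (~140 um horizontal span), 25 % overlap, ~2 molecules per
    frame plus 2 lambda standards per channel, read-noise sigma of one
    tenth of the background. ``kb_per_px`` is the DNA contour length per
    pixel (0.30 kb at 100 nm/pixel for ~85 %-stretched B-DNA).
    """

    frame_shape: tuple[int, int] = (1040, 1392)
    n_frames: int = 10
    overlap_frac: float = 0.25
    pixel_scale_nm: float = 100.0
    adu_per_kb: float = 3000.0
    psf_sigma_px: float = 0.8
    gap_px: int = 3
    cut_end_boost: float = 1.8
    background_adu: float = 100.0
    noise_sigma_adu: float = 10.0
    molecule_density: float = 2.0
    size_range_kb: tuple[float, float] = (30.0, 300.0)
    cut_rate_per_kb: float = 0.02
    standards_per_channel: int = 2
    seed: int = 0
    kb_per_px: float = 0.30
    min_row_spacing_px: int = 15
    perturb_amp_px: float = 2.0
    perturb_wavelength_px: float = 400.0
    min_fragment_px: int = 6
    confuser_mode: bool = False
    channel_id: str = "ch0"
    standard: StandardSpec = field(default_factory=lambda_bsu36i)

    def __post_init__(self) -> None:
        if not 0 < self.overlap_frac < 1:
            raise ValueError("overlap_frac must be in (0, 1)")
        for name in ("adu_per_kb", "psf_sigma_px", "kb_per_px",
                     "pixel_scale_nm"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sigma_adu < 0 or self.background_adu < 0:
            raise ValueError("background and noise must be >= 0")
        if self.n_frames < 1:
            raise ValueError("need at least one frame")

    @property
    def advance_px(self) -> int:
        """Nominal stage advance between frames, in columns."""
        return round((1.0 - self.overlap_frac) * self.frame_shape[1])

    @property
    def channel_cols(self) -> int:
        return self.frame_shape[1] + (self.n_frames - 1) * self.advance_px


@dataclass
class TrueMolecule:
    """Simulator record of one deposited molecule."""

    molecule_id: str
    is_standard: bool
    fragment_sizes_kb: list[float]
    col_start: int
    centerline_rows: np.ndarray  # float row per column over the molecule extent
    cut_positions_col: list[int]  # channel columns of the cut centres
    fragment_intervals: list[tuple[int, int]]  # rendered (lo, hi) inclusive

    @property
    def size_kb(self) -> float:
        return float(sum(self.fragment_sizes_kb))

    @property
    def n_fragments(self) -> int:
        return len(self.fragment_sizes_kb)


@dataclass
class GroundTruth:
    """Everything the simulator knows about the rendered channel."""

    molecules: list[TrueMolecule]
    speckles: list[tuple[int, int]]
    params: SimulationParams

    @property
    def n_standards(self) -> int:
        return sum(m.is_standard for m in self.molecules)


def render_fragment(
    canvas: np.ndarray,
    centerline: tuple[np.ndarray, np.ndarray],
    size_kb: float,
    params: SimulationParams,
) -> np.ndarray:
    """Add one fragment's fluorescence to ``canvas`` (in place).

    ``centerline`` is ``(cols, rows)`` with integer columns and float rows.
    The fragment's total added intensity is exactly
    ``adu_per_kb * size_kb``, distributed along the centerline (end columns
    weighted up by ``cut_end_boost`` to mimic coil relaxation, total
    conserved) and transversely as a discrete Gaussian of sigma
    ``psf_sigma_px`` normalized per column.
    """
    cols, rows = centerline
    cols = np.asarray(cols, dtype=np.int64)
    rows = np.asarray(rows, dtype=np.float64)
    half = max(1, math.ceil(4.0 * params.psf_sigma_px))
    if (
        cols.min() < 0
        or cols.max() >= canvas.shape[1]
        or rows.min() - half < 0
        or rows.max() + half >= canvas.shape[0]
    ):
        raise ValueError("fragment centerline (plus its profile) exceeds the canvas")
    n = cols.size
    weights = np.ones(n, dtype=np.float64)
    n_end = min(2, n)
    weights[:n_end] *= params.cut_end_boost
    weights[-n_end:] *= params.cut_end_boost
    weights /= weights.sum()
    col_intensity = weights * params.adu_per_kb * size_kb

    r0 = np.rint(rows).astype(np.int64)
    frac = rows - r0
    j = np.arange(-half, half + 1)
    # per-column discrete Gaussian centred on the (sub-pixel) ridge row
    prof = np.exp(-((j[None, :] - frac[:, None]) ** 2) / (2.0 * params.psf_sigma_px**2))
    prof /= prof.sum(axis=1, keepdims=True)
    target_rows = r0[:, None] + j[None, :]
    np.add.at(
        canvas,
        (target_rows.ravel(), np.repeat(cols, j.size)),
        (prof * col_intensity[:, None]).ravel(),
    )
    return canvas


def _sample_fragments_kb(
    rng: np.random.Generator, size_kb: float, params: SimulationParams
) -> list[float]:
    """Fragment sizes from a Poisson cut process, avoiding tiny fragments."""
    min_kb = params.min_fragment_px * params.kb_per_px
    for _ in range(200):
        n_cuts = rng.poisson(params.cut_rate_per_kb * size_kb)
        cuts = np.sort(rng.uniform(0.0, size_kb, size=n_cuts))
        bounds = np.concatenate([[0.0], cuts, [size_kb]])
        sizes = np.diff(bounds)
        if np.all(sizes >= min_kb):
            return [float(s) for s in sizes]
    # fall back to an uncut molecule rather than looping forever
    return [float(size_kb)]


def _place_rows(
    rng: np.random.Generator, n: int, params: SimulationParams
) -> list[int]:
    half = max(1, math.ceil(4.0 * params.psf_sigma_px))
    lo = half + 3 + math.ceil(params.perturb_amp_px)
    hi = params.frame_shape[0] - 1 - lo
    rows: list[int] = []
    for _ in range(n):
        for _attempt in range(500):
            r = int(rng.integers(lo, hi + 1))
            if all(abs(r - other) >= params.min_row_spacing_px for other in rows):
                rows.append(r)
                break
        else:
            raise ValueError(
                "molecule density too high: cannot place molecules with the "
                "required minimum row spacing"
            )
    return rows


def _build_molecule(
    rng: np.random.Generator,
    molecule_id: str,
    is_standard: bool,
    sizes_kb: list[float],
    row0: int,
    params: SimulationParams,
) -> TrueMolecule:
    size_kb = sum(sizes_kb)
    length_px = max(round(size_kb / params.kb_per_px), params.min_fragment_px)
    margin = 8
    max_start = params.channel_cols - length_px - margin
    if max_start <= margin:
        raise ValueError("molecule longer than the channel")
    col_start = int(rng.integers(margin, max_start + 1))
    x = np.arange(length_px, dtype=np.float64)
    phase = rng.uniform(0.0, 2.0 * math.pi)
    rows = row0 + params.perturb_amp_px * np.sin(
        2.0 * math.pi * x / params.perturb_wavelength_px + phase
    )
    # fragment boundaries along the molecule, in local pixels
    cum = np.concatenate([[0.0], np.cumsum(sizes_kb)])
    bounds_px = np.rint(cum / size_kb * length_px).astype(int)
    g_left = params.gap_px // 2
    g_right = params.gap_px - g_left
    intervals = []
    cuts = []
    for i in range(len(sizes_kb)):
        lo = bounds_px[i] + (g_right if i > 0 else 0)
        hi = bounds_px[i + 1] - 1 - (g_left if i < len(sizes_kb) - 1 else 0)
        if hi - lo + 1 < 3:
            raise ValueError("fragment too short to render after gap carving")
        intervals.append((col_start + lo, col_start + hi))
        if i > 0:
            cuts.append(col_start + int(bounds_px[i]))
    return TrueMolecule(
        molecule_id=molecule_id,
        is_standard=is_standard,
        fragment_sizes_kb=list(sizes_kb),
        col_start=col_start,
        centerline_rows=rows,
        cut_positions_col=cuts,
        fragment_intervals=intervals,
    )


def simulate_channel(
    params: SimulationParams,
) -> tuple[list[Frame], GroundTruth]:
    """Render a full microchannel as overlapping frames plus ground truth.

    Standards (``standards_per_channel`` copies of ``params.standard``) and
    genomic molecules (count ``molecule_density * n_frames``, sizes uniform
    in ``size_range_kb``, cuts from a Poisson process of rate
    ``cut_rate_per_kb``) are deposited at rows separated by at least
    ``min_row_spacing_px``. Frames advance by ``(1-overlap_frac) * width``
    columns; noiseless overlap regions are therefore pixel-identical.
    Fully reproducible from ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    n_genomic = round(params.molecule_density * params.n_frames)
    n_total = n_genomic + params.standards_per_channel
    n_distractors = 1 if params.confuser_mode else 0
    rows0 = _place_rows(rng, n_total + n_distractors, params)

    molecules: list[TrueMolecule] = []
    idx = 0
    for _ in range(params.standards_per_channel):
        molecules.append(
            _build_molecule(
                rng,
                f"std_{idx:04d}",
                True,
                list(params.standard.fragment_sizes_kb),
                rows0[idx],
                params,
            )
        )
        idx += 1
    for _ in range(n_genomic):
        size = float(rng.uniform(*params.size_range_kb))
        sizes = _sample_fragments_kb(rng, size, params)
        molecules.append(
            _build_molecule(rng, f"mol_{idx:04d}", False, sizes, rows0[idx], params)
        )
        idx += 1

    scene = np.zeros((params.frame_shape[0], params.channel_cols), dtype=np.float64)
    for mol in molecules:
        for (lo, hi), frag_kb in zip(mol.fragment_intervals, mol.fragment_sizes_kb):
            cols = np.arange(lo, hi + 1)
            rows = mol.centerline_rows[cols - mol.col_start]
            render_fragment(scene, (cols, rows), frag_kb, params)

    speckles: list[tuple[int, int]] = []
    if params.confuser_mode:
        # crossing distractor ridge at a deliberately steep orientation
        cross_row = rows0[-1]
        span = min(400, params.channel_cols - 20)
        c0 = int(rng.integers(8, params.channel_cols - span - 8))
        cols = np.arange(c0, c0 + span)
        slope = math.tan(math.radians(12.0))
        rows = cross_row + slope * (cols - c0) - slope * span / 2.0
        half = max(1, math.ceil(4.0 * params.psf_sigma_px))
        rows = np.clip(rows, half + 1, params.frame_shape[0] - half - 2)
        render_fragment(scene, (cols, rows), span * params.kb_per_px, params)
        # bright speckles adjacent to molecules
        # one row below the centerline: bright enough to flag, close enough
        # that the skeleton stays connected through the brightened jog
        speckle_adu = 10.0 * params.adu_per_kb * params.kb_per_px
        genomic = [m for m in molecules if not m.is_standard]
        for mol in genomic[: min(3, len(genomic))]:
            lo, hi = mol.fragment_intervals[0]
            col = int(rng.integers(lo + 2, hi - 2))
            row = int(round(mol.centerline_rows[col - mol.col_start])) + 1
            scene[row, col : col + 2] += speckle_adu
            speckles.append((row, col))

    frames: list[Frame] = []
    advance = params.advance_px
    for k in range(params.n_frames):
        sub = scene[:, k * advance : k * advance + params.frame_shape[1]]
        img = sub + params.background_adu
        if params.noise_sigma_adu > 0:
            img = img + rng.normal(0.0, params.noise_sigma_adu, size=sub.shape)
        img = np.clip(np.rint(img), 0, 65535).astype(np.uint16)
        frames.append(
            Frame(
                pixels=img,
                frame_index=k,
                channel_id=params.channel_id,
                pixel_scale_nm=params.pixel_scale_nm,
            )
        )
    truth = GroundTruth(molecules=molecules, speckles=speckles, params=params)
    return frames, truth


def write_fixture(
    frames: list[Frame], truth: GroundTruth, directory: str | Path
) -> Path:
    """Write a fixture directory: per-frame TIFFs, manifest, truth table.

    The manifest (``manifest.tsv``: channel_id, frame_index, relative path)
    is what the processing pipeline consumes; ``truth.tsv`` records
    molecule_id, is_standard and the comma-separated true fragment sizes in
    kb. Returns the manifest path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    lines = []
    for frame in frames:
        name = f"{frame.channel_id}_f{frame.frame_index:03d}.tif"
        tifffile.imwrite(directory / name, frame.pixels)
        lines.append(f"{frame.channel_id}\t{frame.frame_index}\t{name}")
    manifest = directory / "manifest.tsv"
    manifest.write_text("\n".join(lines) + "\n")
    truth_lines = ["#molecule_id\tis_standard\tfragment_sizes_kb"]
    for mol in truth.molecules:
        sizes = ",".join(f"{s:.4f}" for s in mol.fragment_sizes_kb)
        truth_lines.append(f"{mol.molecule_id}\t{int(mol.is_standard)}\t{sizes}")
    (directory / "truth.tsv").write_text("\n".join(truth_lines) + "\n")
    return manifest
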