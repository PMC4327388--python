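"""Synthetic multi-channel fields of diffraction-limited punctae.

The simulator emulates the kind of images the analysis is designed for:
sparse, diffraction-limited fluorescent spots (endosomes, vesicles) on a
noisy camera background, imaged in two or more channels whose spot
populations overlap by a *known* fraction.  Every scene carries its ground
truth (positions, amplitudes, pairings), so detection accuracy and
colocalisation recovery can be scored exactly.

Model
-----
* Spot positions are complete spatial randomness (uniform) within the field,
  subject to a minimum separation within each channel so individual spots
  remain resolvable.
* A directed pair (a, b) with colocalised fraction f places ``round(f*n_a)``
  channel-b spots at their channel-a partner's position plus an isotropic
  Gaussian displacement of standard deviation ``jitter_nm`` (0 = perfect
  colocalisation).
* The point-spread function is an isotropic 2D Gaussian; pixel values are
  the PSF integrated over each pixel (so a spot of amplitude A and width
  sigma contributes A*2*pi*sigma^2 photons in total).
* Camera noise is Poisson on signal + background, optionally followed by
  additive Gaussian read noise; output is quantised to 16 bits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import erf

from .image import PixelGrid

__all__ = [
    "PsfModel",
    "SceneTruth",
    "SimulationError",
    "generate_scene",
    "render_channel",
    "integrated_gaussian",
    "write_scene",
    "read_truth_csv",
]


class SimulationError(RuntimeError):
    """Scene generation could not satisfy its constraints."""


@dataclass(frozen=True)
class PsfModel:
    """Point-spread function and camera-noise model.

    Parameters
    ----------
    sigma_nm:
        Standard deviation of the Gaussian PSF, in nm (~100 nm emulates a
        diffraction-limited widefield spot).
    background:
        Mean background level in photons per pixel.
    poisson:
        Apply Poisson noise to signal + background.
    read_noise_sd:
        Standard deviation of additive Gaussian read noise (photons);
        0 disables it.
    """

    sigma_nm: float = 100.0
    background: float = 100.0
    poisson: bool = True
    read_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if not (self.sigma_nm > 0):
            raise SimulationError(f"sigma_nm must be > 0, got {self.sigma_nm}")
        if self.background < 0:
            raise SimulationError(f"background must be >= 0, got {self.background}")
        if self.read_noise_sd < 0:
            raise SimulationError("read_noise_sd must be >= 0")


@dataclass
class SceneTruth:
    """Ground truth for one simulated field.

    ``positions[channel]`` is an (n, 2) array of (x, y) pixel coordinates;
    ``pairs[(a, b)]`` lists index pairs (i_a, i_b) of truly colocalised
    particles for the directed channel pair (a, b).
    """

    field_shape: tuple[int, int]  # (height, width) in pixels
    pixel_size_nm: float
    channels: tuple[str, ...]
    positions: dict[str, np.ndarray]
    amplitudes: dict[str, np.ndarray]
    pairs: dict[tuple[str, str], list[tuple[int, int]]] = field(default_factory=dict)
    seed: int | None = None

    def n_particles(self, channel: str) -> int:
        return len(self.positions[channel])

    def true_coloc_fraction(self, source: str, target: str) -> float:
        """Fraction of source-channel particles with a true partner in target."""
        n = self.n_particles(source)
        if n == 0:
            raise SimulationError(f"channel {source!r} has no particles")
        return len(self.pairs.get((source, target), [])) / n

    def pair_displacements_nm(self, source: str, target: str) -> np.ndarray:
        """Realised centre-to-centre distances of the true pairs, in nm."""
        idx = self.pairs.get((source, target), [])
        if not idx:
            return np.empty(0)
        ia, ib = np.array(idx).T
        d = self.positions[source][ia] - self.positions[target][ib]
        return np.hypot(d[:, 0], d[:, 1]) * self.pixel_size_nm

    def to_frame(self) -> pd.DataFrame:
        """Flatten the truth to one row per particle.

        ``pair_id`` links the two partners of a true pair (-1 = unpaired).
        """
        pair_id: dict[str, np.ndarray] = {
            ch: np.full(self.n_particles(ch), -1, dtype=int) for ch in self.channels
        }
        k = 0
        for (a, b), idx in sorted(self.pairs.items()):
            for ia, ib in idx:
                pair_id[a][ia] = k
                pair_id[b][ib] = k
                k += 1
        rows = []
        for ch in self.channels:
            pos = self.positions[ch]
            rows.append(
                pd.DataFrame(
                    {
                        "channel": ch,
                        "x_px": pos[:, 0],
                        "y_px": pos[:, 1],
                        "amplitude": self.amplitudes[ch],
                        "pair_id": pair_id[ch],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def _sample_min_separation(
    rng: np.random.Generator,
    n: int,
    lo: np.ndarray,
    hi: np.ndarray,
    min_sep_px: float,
    fixed: np.ndarray | None = None,
    max_attempts_per_point: int = 200,
) -> np.ndarray:
    """Rejection-sample n uniform points keeping min_sep_px to all accepted
    points (and to ``fixed`` if given)."""
    placed: list[np.ndarray] = [] if fixed is None else [p for p in fixed]
    out: list[np.ndarray] = []
    budget = max_attempts_per_point * max(n, 1)
    while len(out) < n and budget > 0:
        budget -= 1
        p = rng.uniform(lo, hi)
        if min_sep_px > 0 and placed:
            d2 = np.min(np.sum((np.asarray(placed) - p) ** 2, axis=1))
            if d2 < min_sep_px**2:
                continue
        placed.append(p)
        out.append(p)
    if len(out) < n:
        raise SimulationError(
            f"could not place {n} particles with min_separation "
            f"{min_sep_px:.2f} px; achieved {len(out)}"
        )
    return np.asarray(out).reshape(n, 2)


def generate_scene(
    n_per_channel: int | Sequence[int],
    field_shape: tuple[int, int] = (512, 512),
    channels: Sequence[str] = ("ch0", "ch1"),
    coloc_fraction: float | Mapping[tuple[int, int], float] = 0.0,
    jitter_nm: float = 0.0,
    min_separation_nm: float = 400.0,
    pixel_size_nm: float = 107.5,
    amplitude: float = 1000.0,
    edge_margin_px: float = 0.0,
    seed: int | None = None,
) -> SceneTruth:
    """Generate ground-truth particle positions for a multi-channel field.

    Parameters
    ----------
    n_per_channel:
        Particle count per channel (scalar applies to all channels).
    coloc_fraction:
        Either a scalar fraction for the directed pair (channel 0 ->
        channel 1), or a mapping {(i, j): fraction} over channel indices.
        For each pair, ``round(fraction * n_i)`` channel-j particles are
        placed at a channel-i partner (plus jitter); the rest are uniform.
    jitter_nm:
        Standard deviation of the isotropic Gaussian displacement between
        true partners (0 = identical coordinates).
    min_separation_nm:
        Minimum centre-to-centre distance *within* each channel; the default
        of 400 nm (4x a typical 100 nm PSF sigma) keeps spots individually
        resolvable.
    amplitude:
        Peak amplitude (photons) assigned to every particle.
    edge_margin_px:
        Keep all particles at least this many pixels away from the field
        edge (useful when scoring detectors that discard a border strip).
    """
    channels = tuple(channels)
    n_ch = len(channels)
    if np.isscalar(n_per_channel):
        counts = [int(n_per_channel)] * n_ch
    else:
        counts = [int(v) for v in n_per_channel]
        if len(counts) != n_ch:
            raise SimulationError("n_per_channel length does not match channels")
    if any(c < 0 for c in counts):
        raise SimulationError("particle counts must be >= 0")
    if min_separation_nm < 0:
        raise SimulationError("min_separation_nm must be >= 0")
    if jitter_nm < 0:
        raise SimulationError("jitter_nm must be >= 0")

    if np.isscalar(coloc_fraction):
        frac_map: dict[tuple[int, int], float] = {}
        if float(coloc_fraction) != 0.0:
            if n_ch < 2:
                raise SimulationError(
                    "coloc_fraction > 0 requires at least two channels"
                )
            frac_map = {(0, 1): float(coloc_fraction)}
    else:
        frac_map = {tuple(k): float(v) for k, v in coloc_fraction.items()}
    for (i, j), f in frac_map.items():
        if not (0 <= f <= 1):
            raise SimulationError(f"coloc_fraction for pair {(i, j)} must be in [0, 1], got {f}")
        if i == j or not (0 <= i < n_ch and 0 <= j < n_ch):
            raise SimulationError(f"invalid channel pair {(i, j)}")

    h, w = field_shape
    rng = np.random.default_rng(seed)
    min_sep_px = min_separation_nm / pixel_size_nm
    jitter_px = jitter_nm / pixel_size_nm
    # pixel centres span [0, dim-1]; the field extends half a pixel beyond
    lo = np.array([-0.5 + edge_margin_px, -0.5 + edge_margin_px])
    hi = np.array([w - 0.5 - edge_margin_px, h - 0.5 - edge_margin_px])
    if np.any(hi <= lo):
        raise SimulationError("edge_margin_px leaves no room in the field")

    positions: dict[str, np.ndarray] = {}
    pairs: dict[tuple[str, str], list[tuple[int, int]]] = {}
    # channels that are a pairing target inherit partner positions first
    targets_of: dict[int, list[tuple[int, float]]] = {}
    for (i, j), f in frac_map.items():
        targets_of.setdefault(j, []).append((i, f))

    for j, ch in enumerate(channels):
        n = counts[j]
        paired_pos: list[np.ndarray] = []
        for i, f in targets_of.get(j, []):
            src_ch = channels[i]
            if src_ch not in positions:
                raise SimulationError(
                    f"pairing ({i}, {j}) requires channel {i} to be generated first; "
                    "order pairs so the source channel index precedes the target"
                )
            n_pairs = int(round(f * counts[i]))
            if n_pairs > counts[i] or len(paired_pos) + n_pairs > n:
                raise SimulationError(
                    f"cannot form {n_pairs} pairs for channel pair ({i}, {j}) "
                    f"with counts {counts[i]} and {n}"
                )
            src_idx = rng.choice(counts[i], size=n_pairs, replace=False)
            src_idx.sort()
            plist = pairs.setdefault((src_ch, ch), [])
            for ia in src_idx:
                while True:
                    p = positions[src_ch][ia]
                    if jitter_px > 0:
                        p = p + rng.normal(0.0, jitter_px, size=2)
                    if np.all(p >= lo) and np.all(p <= hi):
                        break
                plist.append((int(ia), len(paired_pos)))
                paired_pos.append(p)
        n_free = n - len(paired_pos)
        fixed = np.asarray(paired_pos) if paired_pos else None
        free = _sample_min_separation(rng, n_free, lo, hi, min_sep_px, fixed=fixed)
        pos = np.vstack([np.asarray(paired_pos).reshape(-1, 2), free])
        positions[ch] = pos

    amplitudes = {ch: np.full(counts[j], float(amplitude)) for j, ch in enumerate(channels)}
    return SceneTruth(
        field_shape=(h, w),
        pixel_size_nm=pixel_size_nm,
        channels=channels,
        positions=positions,
        amplitudes=amplitudes,
        pairs=pairs,
        seed=seed,
    )


def integrated_gaussian(
    shape: tuple[int, int],
    x0: float,
    y0: float,
    amplitude: float,
    sigma_px: float,
    support_sigmas: float = 6.0,
) -> np.ndarray:
    """Noiseless image of one spot: the Gaussian PSF integrated per pixel.

    Pixel (x, y) receives ``amplitude * 2*pi*sigma^2 * Fx(x) * Fy(y)`` where
    Fx/Fy are the 1D Gaussian masses over the unit pixel, so the image sums
    to ``amplitude * 2*pi*sigma_px**2`` (up to the finite support window).
    Spots whose support lies entirely outside the field contribute nothing.
    """
    h, w = shape
    out = np.zeros((h, w))
    r = int(np.ceil(support_sigmas * sigma_px)) + 1
    xlo, xhi = int(np.floor(x0)) - r, int(np.floor(x0)) + r + 1
    ylo, yhi = int(np.floor(y0)) - r, int(np.floor(y0)) + r + 1
    xlo, xhi = max(xlo, 0), min(xhi, w)
    ylo, yhi = max(ylo, 0), min(yhi, h)
    if xlo >= xhi or ylo >= yhi:
        return out
    xs = np.arange(xlo, xhi)
    ys = np.arange(ylo, yhi)
    s = sigma_px * np.sqrt(2.0)
    fx = 0.5 * (erf((xs + 0.5 - x0) / s) - erf((xs - 0.5 - x0) / s))
    fy = 0.5 * (erf((ys + 0.5 - y0) / s) - erf((ys - 0.5 - y0) / s))
    total = amplitude * 2.0 * np.pi * sigma_px**2
    out[ylo:yhi, xlo:xhi] = total * np.outer(fy, fx)
    return out


def render_channel(
    truth: SceneTruth,
    channel: str,
    psf: PsfModel,
    seed: int | None = None,
    bit_depth: int = 16,
    quantize: bool = True,
) -> PixelGrid:
    """Render one channel of a scene as a camera image.

    The noiseless image is the per-pixel integral of every spot's Gaussian
    PSF plus the flat background; Poisson noise (and optional Gaussian read
    noise) is then applied and the result quantised to ``bit_depth`` bits.
    Set ``quantize=False`` to obtain the continuous (float) image for
    analytic work; noise, if enabled, is still applied.
    """
    if channel not in truth.channels:
        raise SimulationError(f"unknown channel {channel!r}; scene has {truth.channels}")
    sigma_px = psf.sigma_nm / truth.pixel_size_nm
    clean = np.zeros(truth.field_shape)
    for (x0, y0), amp in zip(truth.positions[channel], truth.amplitudes[channel]):
        clean += integrated_gaussian(truth.field_shape, x0, y0, amp, sigma_px)
    clean += psf.background

    img = clean
    if psf.poisson or psf.read_noise_sd > 0:
        rng = np.random.default_rng(seed)
        if psf.poisson:
            img = rng.poisson(clean).astype(float)
        if psf.read_noise_sd > 0:
            img = img + rng.normal(0.0, psf.read_noise_sd, size=img.shape)
    if not quantize:
        return PixelGrid(
            data=np.clip(img, 0, None),
            pixel_size_nm=truth.pixel_size_nm,
            channel=channel,
        )
    max_val = 2**bit_depth - 1
    dtype = np.uint16 if bit_depth > 8 else np.uint8
    data = np.clip(np.rint(img), 0, max_val).astype(dtype)
    return PixelGrid(data=data, pixel_size_nm=truth.pixel_size_nm, channel=channel)


def write_scene(
    truth: SceneTruth,
    out_dir: str | Path,
    psf: PsfModel,
    seed: int | None = None,
) -> dict:
    """Write per-channel TIFFs, a truth CSV and a JSON scene manifest.

    Per-channel render seeds are derived deterministically from ``seed``.
    Returns the manifest mapping.
    """
    from .image import write_tiff  # local import to avoid cycle at module load

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    render_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(truth.channels))]
    tiffs = {}
    for ch, rseed in zip(truth.channels, render_seeds):
        grid = render_channel(truth, ch, psf, seed=rseed)
        path = out_dir / f"{ch}.tif"
        write_tiff(path, grid)
        tiffs[ch] = path.name
    truth_path = out_dir / "truth.csv"
    truth.to_frame().to_csv(truth_path, index=False, float_format="%.6f")
    manifest = {
        "field_shape": list(truth.field_shape),
        "pixel_size_nm": truth.pixel_size_nm,
        "channels": list(truth.channels),
        "n_per_channel": {ch: truth.n_particles(ch) for ch in truth.channels},
        "pairs": {f"{a}->{b}": len(v) for (a, b), v in sorted(truth.pairs.items())},
        "psf": {
            "sigma_nm": psf.sigma_nm,
            "background": psf.background,
            "poisson": psf.poisson,
            "read_noise_sd": psf.read_noise_sd,
        },
        "scene_seed": truth.seed,
        "render_seed": seed,
        "render_seeds_per_channel": dict(zip(truth.channels, render_seeds)),
        "images": tiffs,
        "truth_csv": truth_path.name,
    }
    (out_dir / "scene.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def read_truth_csv(path: str | Path, field_shape: tuple[int, int], pixel_size_nm: float) -> SceneTruth:
    """Reconstruct a SceneTruth from a truth CSV written by :func:`write_scene`."""
    df = pd.read_csv(path)
    channels = tuple(dict.fromkeys(df["channel"]))
    positions = {}
    amplitudes = {}
    pair_rows: dict[int, list[tuple[str, int]]] = {}
    for ch in channels:
        sub = df[df["channel"] == ch].reset_index(drop=True)
        positions[ch] = sub[["x_px", "y_px"]].to_numpy(float)
        amplitudes[ch] = sub["amplitude"].to_numpy(float)
        for i, pid in enumerate(sub["pair_id"]):
            if pid >= 0:
                pair_rows.setdefault(int(pid), []).append((ch, i))
    pairs: dict[tuple[str, str], list[tuple[int, int]]] = {}
    order = {ch: k for k, ch in enumerate(channels)}
    for pid, members in pair_rows.items():
        if len(members) != 2:
            raise SimulationError(f"pair_id {pid} does not have exactly two members")
        members.sort(key=lambda m: order[m[0]])
        (ca, ia), (cb, ib) = members
        pairs.setdefault((ca, cb), []).append((ia, ib))
    for v in pairs.values():
        v.sort()
    return SceneTruth(
        field_shape=tuple(field_shape),
        pixel_size_nm=pixel_size_nm,
        channels=channels,
        positions=positions,
        amplitudes=amplitudes,
        pairs=pairs,
    )
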