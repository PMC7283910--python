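"""Complex eigen-spectra of STE matrices and their coarse-grained grids.

Because an STE matrix is asymmetric its 64 eigenvalues λ = α + βi are
complex; their scatter in the complex plane is the participant's
"fingerprint".  Real and imaginary parts are z-scored per matrix, and the
normalized spectrum is binned into a square grid of cell size θ whose
occupancy counts form the fingerprint histogram used for identification.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass

import numpy as np

from .ste import STEMatrix


def _canonical_order(values: np.ndarray) -> np.ndarray:
    """Sort eigenvalues by descending modulus, then descending real part,
    then non-negative imaginary part first (conjugates pair up adjacently)."""
    order = np.lexsort((-values.imag, -values.real, -np.abs(values)))
    return values[order]


@dataclass
class Spectrum:
    """Eigenvalues of one STE matrix in canonical order."""

    eigenvalues: np.ndarray
    participant_id: int = 0
    task: int = 1
    event: int = 1
    normalized: bool = False

    def __post_init__(self) -> None:
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=complex).ravel()

    @property
    def n(self) -> int:
        return self.eigenvalues.size

    @property
    def vector(self) -> np.ndarray:
        """Canonical real vector: all real parts followed by all imaginary
        parts (length 128 for a 64-channel matrix)."""
        return np.concatenate([self.eigenvalues.real, self.eigenvalues.imag])


def eigen_spectrum(matrix: STEMatrix) -> Spectrum:
    """All eigenvalues of the STE matrix, canonically ordered.

    For a real input matrix the spectrum is checked to be closed under
    conjugation (a property of real-coefficient characteristic polynomials).
    """
    values = matrix.values
    if not np.all(np.isfinite(values)):
        raise ValueError("matrix contains non-finite entries")
    eig = np.linalg.eigvals(values)
    if np.isrealobj(values):
        conj_sorted = _canonical_order(np.conj(eig))
        eig_sorted = _canonical_order(eig)
        if not np.allclose(conj_sorted, eig_sorted, atol=1e-8 * max(1.0, np.abs(eig).max())):
            raise AssertionError("spectrum of a real matrix must be conjugate-closed")
    return Spectrum(
        eigenvalues=_canonical_order(eig),
        participant_id=matrix.participant_id,
        task=matrix.task,
        event=matrix.event,
        normalized=False,
    )


def zscore(spectrum: Spectrum, on_zero_variance: str = "zero") -> Spectrum:
    """Standardize real and imaginary parts independently (mean 0, sample SD 1).

    A component with zero variance cannot be standardized; the documented
    fallback (``on_zero_variance="zero"``) centres it at exactly 0 and warns,
    while ``"error"`` raises instead.
    """
    def _std(x: np.ndarray, name: str) -> np.ndarray:
        sd = x.std(ddof=1) if x.size > 1 else 0.0
        if sd == 0:
            if on_zero_variance == "error":
                raise ValueError(f"zero variance in {name} component")
            warnings.warn(f"zero-variance {name} component left at 0 after centring")
            return np.zeros_like(x)
        return (x - x.mean()) / sd

    re = _std(spectrum.eigenvalues.real, "real")
    im = _std(spectrum.eigenvalues.imag, "imaginary")
    return Spectrum(
        eigenvalues=_canonical_order(re + 1j * im),
        participant_id=spectrum.participant_id,
        task=spectrum.task,
        event=spectrum.event,
        normalized=True,
    )


@dataclass
class SpectrumGrid:
    """2-D occupancy histogram of complex eigenvalues.

    Cell (r, c) covers the half-open square
    ``(α_min + (r−1)θ, α_min + rθ] × (β_min + (c−1)θ, β_min + cθ]`` except
    that the first cell's lower edge is closed, so every point of the range
    is binned.
    """

    theta: float
    real_range: tuple[float, float]
    imag_range: tuple[float, float]
    counts: np.ndarray
    n_clipped: int = 0

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        self.counts = np.asarray(self.counts, dtype=int)

    @property
    def total_mass(self) -> int:
        return int(self.counts.sum())

    def aligned_with(self, other: "SpectrumGrid") -> bool:
        return (
            self.theta == other.theta
            and self.real_range == other.real_range
            and self.imag_range == other.imag_range
            and self.counts.shape == other.counts.shape
        )

    def __add__(self, other: "SpectrumGrid") -> "SpectrumGrid":
        if not self.aligned_with(other):
            raise ValueError("cannot add grids with different theta/ranges")
        return SpectrumGrid(
            theta=self.theta,
            real_range=self.real_range,
            imag_range=self.imag_range,
            counts=self.counts + other.counts,
            n_clipped=self.n_clipped + other.n_clipped,
        )

    def to_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"# theta={self.theta} real_range={self.real_range[0]},{self.real_range[1]} "
                f"imag_range={self.imag_range[0]},{self.imag_range[1]}\n"
            )
            np.savetxt(fh, self.counts, delimiter="\t", fmt="%d")

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "SpectrumGrid":
        with open(path) as fh:
            lines = fh.readlines()
        meta: dict[str, str] = {}
        body = []
        for line in lines:
            if line.startswith("#"):
                for tok in line[1:].split():
                    if "=" in tok:
                        k, _, v = tok.partition("=")
                        meta[k] = v
            else:
                body.append(line)
        rr = tuple(float(x) for x in meta["real_range"].split(","))
        ir = tuple(float(x) for x in meta["imag_range"].split(","))
        counts = np.loadtxt(body, delimiter="\t", ndmin=2).astype(int)
        return cls(theta=float(meta["theta"]), real_range=rr, imag_range=ir, counts=counts)


def _n_cells(lo: float, hi: float, theta: float) -> int:
    span = hi - lo
    if span <= 0:
        return 1
    return int(np.ceil(span / theta - 1e-9))


def _bin_indices(x: np.ndarray, lo: float, n: int, theta: float, clip: bool) -> tuple[np.ndarray, int]:
    # tolerance keeps range endpoints in their nominal cells despite round-off
    tol = 1e-9
    frac = (x - lo) / theta - tol
    idx = np.ceil(frac).astype(int)
    idx[(idx == 0) & (frac >= -2 * tol)] = 1  # closed lower edge of the first cell
    clipped = int(np.sum((idx < 1) | (idx > n)))
    if clipped and not clip:
        raise ValueError("points lie outside the explicit coarse-graining ranges")
    return np.clip(idx, 1, n), clipped


def coarse_grain(
    points: np.ndarray | Spectrum,
    theta: float = 1.0,
    real_range: tuple[float, float] | None = None,
    imag_range: tuple[float, float] | None = None,
    clip: bool = False,
) -> SpectrumGrid:
    """Bin complex eigenvalues into a θ-grid and count occupants per cell.

    Without explicit ranges the grid spans the points' own min/max (the
    per-spectrum reading); with shared ranges, points outside raise unless
    ``clip`` is set, in which case they are counted into the boundary cells
    and tallied in ``n_clipped``.
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    pts = points.eigenvalues if isinstance(points, Spectrum) else np.asarray(points, dtype=complex)
    pts = pts.ravel()
    if pts.size == 0:
        raise ValueError("cannot coarse-grain an empty point set")
    re, im = pts.real, pts.imag
    rr = real_range if real_range is not None else (float(re.min()), float(re.max()))
    ir = imag_range if imag_range is not None else (float(im.min()), float(im.max()))
    n_r = _n_cells(rr[0], rr[1], theta)
    n_i = _n_cells(ir[0], ir[1], theta)
    ri, clip_r = _bin_indices(re, rr[0], n_r, theta, clip)
    ci, clip_i = _bin_indices(im, ir[0], n_i, theta, clip)
    counts = np.zeros((n_r, n_i), dtype=int)
    np.add.at(counts, (ri - 1, ci - 1), 1)
    return SpectrumGrid(
        theta=theta,
        real_range=(float(rr[0]), float(rr[1])),
        imag_range=(float(ir[0]), float(ir[1])),
        counts=counts,
        n_clipped=clip_r + clip_i,
    )
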