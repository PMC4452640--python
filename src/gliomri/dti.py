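"""Diffusion tensor estimation and MD/FA mapping.

The diffusion-weighted signal follows the Stejskal-Tanner mono-exponential
model S = S0 * exp(-b g^T D g) for b-value b (s/mm^2) and unit gradient
direction g. Taking logs makes the six unique tensor elements plus ln S0
linear in the measurements, so the tensor is estimated per voxel by
ordinary least squares on the log-signals; eigendecomposition then yields

    MD = (l1 + l2 + l3) / 3
    FA = sqrt(3/2) * sqrt(sum (li - MD)^2) / sqrt(sum li^2)

with eigenvalues sorted descending. Diffusivities are expressed in um^2/s
throughout (so b must be converted: b[s/mm^2] * D[um^2/s] * 1e-6 is the
dimensionless exponent).

The acquisition emulated by default uses one b = 0 volume plus b = 300 and
1400 s/mm^2 in seven directions; vendors rarely publish their direction
tables, so the default set below (the six (1,1,0)-family directions plus
the body diagonal) is documented in the scheme file and any user-supplied
set is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .volumes import ImageVolume, ParametricMap, ROIMask

__all__ = [
    "DiffusionScheme",
    "TensorEigen",
    "TensorField",
    "default_directions",
    "default_scheme",
    "build_design_matrix",
    "fit_tensor",
    "md_from_eigenvalues",
    "fa_from_eigenvalues",
    "md_fa_maps",
]

# b [s/mm^2] * D [um^2/s] -> dimensionless exponent
_B_D_SCALE = 1e-6

_UNIT_TOL = 1e-6


def default_directions() -> np.ndarray:
    """The default 7-direction set: (1,1,0)-family pairs plus (1,1,1)/sqrt(3)."""
    dirs = np.array(
        [
            [1, 1, 0],
            [1, 0, 1],
            [0, 1, 1],
            [1, -1, 0],
            [1, 0, -1],
            [0, 1, -1],
            [1, 1, 1],
        ],
        dtype=float,
    )
    return dirs / np.linalg.norm(dirs, axis=1, keepdims=True)


@dataclass
class DiffusionScheme:
    """Per-volume b-values (s/mm^2) and unit gradient directions.

    Diffusion gradient separation (Delta) and duration (delta) are carried
    as acquisition metadata.
    """

    bvals: np.ndarray                  # (N,)
    bvecs: np.ndarray                  # (N, 3), unit norm where b > 0
    big_delta_ms: float = 16.0
    small_delta_ms: float = 4.0

    def __post_init__(self) -> None:
        self.bvals = np.atleast_1d(np.asarray(self.bvals, dtype=float))
        self.bvecs = np.atleast_2d(np.asarray(self.bvecs, dtype=float))
        if self.bvecs.shape != (self.bvals.size, 3):
            raise ValueError(
                f"expected {self.bvals.size} direction 3-vectors, got array of "
                f"shape {self.bvecs.shape}"
            )
        if (self.bvals < 0).any():
            raise ValueError("b-values must be non-negative")
        if not (self.bvals == 0).any():
            raise ValueError("scheme needs at least one b = 0 volume")
        weighted = self.bvals > 0
        norms = np.linalg.norm(self.bvecs[weighted], axis=1)
        if norms.size and np.abs(norms - 1.0).max() > _UNIT_TOL:
            worst = float(np.abs(norms - 1.0).max())
            raise ValueError(
                f"gradient directions must be unit-norm (worst deviation {worst:.2e})"
            )

    def __len__(self) -> int:
        return self.bvals.size

    def to_file(self, path: str | Path) -> Path:
        """Write a whitespace-delimited ``b gx gy gz`` scheme file."""
        path = Path(path)
        lines = ["# b[s/mm^2] gx gy gz"]
        for b, g in zip(self.bvals, self.bvecs):
            lines.append(f"{b:.6g} {g[0]:.12g} {g[1]:.12g} {g[2]:.12g}")
        path.write_text("\n".join(lines) + "\n")
        return path

    @classmethod
    def from_file(cls, path: str | Path, **meta: float) -> "DiffusionScheme":
        rows = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"{path}: malformed scheme line {line!r}")
            rows.append([float(p) for p in parts])
        arr = np.asarray(rows, dtype=float)
        return cls(bvals=arr[:, 0], bvecs=arr[:, 1:], **meta)


def default_scheme(bvals: tuple[float, ...] = (300.0, 1400.0)) -> DiffusionScheme:
    """One basal b = 0 volume plus each shell in the default 7 directions."""
    dirs = default_directions()
    b_list = [0.0]
    g_list = [np.zeros(3)]
    for b in bvals:
        for g in dirs:
            b_list.append(float(b))
            g_list.append(g)
    return DiffusionScheme(bvals=np.array(b_list), bvecs=np.array(g_list))


def build_design_matrix(scheme: DiffusionScheme) -> np.ndarray:
    """Log-linear design matrix of the Stejskal-Tanner system.

    Row i maps the unknowns (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz, ln S0) onto
    ln S_i and reads

        [-b gx^2, -b gy^2, -b gz^2, -2b gx gy, -2b gx gz, -2b gy gz, 1]

    with b rescaled so diffusivities come out in um^2/s.
    """
    b = scheme.bvals * _B_D_SCALE
    g = scheme.bvecs
    design = np.column_stack(
        [
            -b * g[:, 0] ** 2,
            -b * g[:, 1] ** 2,
            -b * g[:, 2] ** 2,
            -2 * b * g[:, 0] * g[:, 1],
            -2 * b * g[:, 0] * g[:, 2],
            -2 * b * g[:, 1] * g[:, 2],
            np.ones(len(scheme)),
        ]
    )
    rank = np.linalg.matrix_rank(design)
    if rank < 7:
        raise ValueError(
            f"diffusion scheme is rank-deficient (design rank {rank} < 7): "
            "need at least 6 non-collinear weighted directions plus b = 0"
        )
    return design


@dataclass
class TensorEigen:
    """Eigen-decomposition of one diffusion tensor (descending eigenvalues)."""

    evals: np.ndarray    # (3,), um^2/s, sorted descending
    evecs: np.ndarray    # (3, 3), columns are the principal directions

    def __post_init__(self) -> None:
        self.evals = np.asarray(self.evals, dtype=float)
        self.evecs = np.asarray(self.evecs, dtype=float)
        if not (self.evals[0] >= self.evals[1] >= self.evals[2]):
            raise ValueError("eigenvalues must be sorted descending")
        if np.abs(self.evecs.T @ self.evecs - np.eye(3)).max() > 1e-8:
            raise ValueError("eigenvectors must be orthonormal")


@dataclass
class TensorField:
    """Per-voxel tensor estimates over a mask."""

    tensors: np.ndarray          # (X, Y, Z, 3, 3)
    s0: np.ndarray               # (X, Y, Z) fitted b=0 amplitude
    valid: np.ndarray            # (X, Y, Z) bool: fit defined
    clamped: np.ndarray          # (X, Y, Z) bool: had a negative eigenvalue
    voxel_size: tuple[float, float, float]


def fit_tensor(series: ImageVolume, scheme: DiffusionScheme,
               mask: ROIMask) -> TensorField:
    """Ordinary least-squares tensor fit on log-signals, voxel by voxel.

    Voxels containing any non-positive signal are flagged invalid (the log
    model is undefined there; substituting an epsilon would bias the
    tensor). Negative eigenvalues of the fitted tensor are clamped to zero
    with the voxel recorded in ``clamped``.
    """
    data = series.data
    if data.ndim != 4:
        raise ValueError("diffusion series must be 4D")
    if data.shape[3] != len(scheme):
        raise ValueError(
            f"series has {data.shape[3]} volumes but scheme lists {len(scheme)}"
        )
    if mask.data.shape != data.shape[:3]:
        raise ValueError("mask shape does not match series grid")
    if not mask.data.any():
        raise ValueError("mask selects no voxels")

    design = build_design_matrix(scheme)
    vox = mask.data
    signals = data[vox]                      # (V, N)
    positive = (signals > 0).all(axis=1)     # log defined

    coeffs = np.zeros((signals.shape[0], 7))
    if positive.any():
        logs = np.log(signals[positive])     # (Vp, N)
        sol, *_ = np.linalg.lstsq(design, logs.T, rcond=None)
        coeffs[positive] = sol.T

    shape = data.shape[:3]
    tensors = np.zeros(shape + (3, 3))
    s0 = np.zeros(shape)
    valid = np.zeros(shape, bool)
    clamped = np.zeros(shape, bool)

    d = coeffs
    t = np.empty((signals.shape[0], 3, 3))
    t[:, 0, 0] = d[:, 0]
    t[:, 1, 1] = d[:, 1]
    t[:, 2, 2] = d[:, 2]
    t[:, 0, 1] = t[:, 1, 0] = d[:, 3]
    t[:, 0, 2] = t[:, 2, 0] = d[:, 4]
    t[:, 1, 2] = t[:, 2, 1] = d[:, 5]

    tensors[vox] = t
    s0[vox] = np.exp(d[:, 6])
    vmask = np.zeros(signals.shape[0], bool)
    vmask[positive] = True
    valid[vox] = vmask

    # clamp negative eigenvalues to 0, re-composing the tensor
    if positive.any():
        evals, evecs = np.linalg.eigh(t[positive])
        neg = (evals < 0).any(axis=1)
        if neg.any():
            ev = np.clip(evals[neg], 0.0, None)
            fixed = np.einsum("vij,vj,vkj->vik", evecs[neg], ev, evecs[neg])
            idx = np.where(positive)[0][neg]
            t[idx] = fixed
            tensors[vox] = t
            cmask = np.zeros(signals.shape[0], bool)
            cmask[idx] = True
            clamped[vox] = cmask

    return TensorField(tensors=tensors, s0=s0, valid=valid, clamped=clamped,
                       voxel_size=series.voxel_size)


def _evals_array(e) -> np.ndarray:
    if isinstance(e, TensorEigen):
        return e.evals
    return np.asarray(e, dtype=float)


def md_from_eigenvalues(e) -> np.ndarray | float:
    """Mean diffusivity: the eigenvalue mean (um^2/s)."""
    ev = _evals_array(e)
    return ev.mean(axis=-1)


def fa_from_eigenvalues(e, printed_variant: bool = False) -> np.ndarray | float:
    """Fractional anisotropy in [0, 1] from the eigenvalue spectrum.

    Standard normalized form: sqrt(3/2) * ||l - MD|| / ||l||. An all-zero
    spectrum has no defined anisotropy and returns NaN (callers flag the
    voxel rather than raise).

    ``printed_variant`` evaluates an alternative, non-normalized expression
    sqrt(sum (li - MD)^2) / (2 sum li^2) kept for comparison only; it is
    not bounded by 1 and is never used in the pipeline.
    """
    ev = _evals_array(e)
    md = ev.mean(axis=-1, keepdims=True)
    num = np.sqrt(((ev - md) ** 2).sum(axis=-1))
    sq = (ev**2).sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        if printed_variant:
            out = num / (2.0 * sq)
        else:
            out = np.sqrt(1.5) * num / np.sqrt(sq)
    return np.where(sq > 0, out, np.nan) if np.ndim(out) else (
        float(out) if sq > 0 else float("nan"))


def md_fa_maps(field: TensorField, mask: ROIMask | None = None,
               printed_fa_variant: bool = False) -> tuple[ParametricMap, ParametricMap]:
    """Eigendecompose the tensor field and map MD (um^2/s) and FA (unitless)."""
    vox = field.valid if mask is None else (field.valid & mask.data)
    if not vox.any():
        raise ValueError("no valid voxels to map")
    evals = np.linalg.eigvalsh(field.tensors[vox])   # ascending
    evals = evals[:, ::-1]
    md_vals = md_from_eigenvalues(evals)
    fa_vals = fa_from_eigenvalues(evals, printed_variant=printed_fa_variant)

    shape = field.tensors.shape[:3]
    md = np.zeros(shape)
    fa = np.zeros(shape)
    md[vox] = md_vals
    fa[vox] = np.nan_to_num(fa_vals, nan=0.0)
    fa_valid = vox.copy()
    fa_valid[vox] = ~np.isnan(fa_vals)

    md_map = ParametricMap(data=md, voxel_size=field.voxel_size,
                           unit="um^2/s", quantity="MD", valid=vox)
    fa_map = ParametricMap(data=fa, voxel_size=field.voxel_size,
                           unit="unitless", quantity="FA", valid=fa_valid)
    return md_map, fa_map
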