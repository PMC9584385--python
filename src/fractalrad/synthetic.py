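"""Synthetic phantoms and cohorts for exercising the full analysis stack.

Two families of generators live here:

* geometric phantoms with analytically known properties — exact digital
  primitives (cube, slab, line, ball), the Menger sponge (box dimension
  log20/log3), and a tumour-like "blob" whose border irregularity and internal
  gappiness are tunable knobs; and
* tabular cohorts emulating a two-group radiogenomic study of grade 2
  meningiomas (TERT-promoter wildtype vs mutant), with per-group Gaussian
  continuous variables and Bernoulli binary findings. The defaults are the
  published group summaries of that study population: 7/48 mutant prevalence,
  FD 1.74±0.16 vs 1.88±0.16, lacunarity 5.51±0.41 vs 6.01±0.64, and matching
  clinical/imaging covariates.

Every generator is a pure function of its arguments including the seed.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ParameterError
from .mask import VoxelMask

__all__ = [
    "make_primitive",
    "make_menger_sponge",
    "make_blob",
    "CohortSpec",
    "generate_cohort",
    "simulate_logit_cohort",
    "TWO_FEATURE_MODEL",
    "TABLE_CONTINUOUS",
    "TABLE_BINARY",
    "TABLE_PATHOLOGY",
]

# Published two-group summaries (wildtype, mutant) used as generator defaults.
# Continuous: (mean, SD) per group. Binary: proportion with the finding per group.
TABLE_CONTINUOUS: dict[str, tuple[tuple[float, float], tuple[float, float]]] = {
    "age": ((56.29, 14.95), (69.57, 10.33)),
    "max_diameter_cm": ((4.82, 1.48), (6.15, 1.33)),
    "fd": ((1.74, 0.16), (1.88, 0.16)),
    "lacunarity": ((5.51, 0.41), (6.01, 0.64)),
}
TABLE_PATHOLOGY: dict[str, tuple[tuple[float, float], tuple[float, float]]] = {
    "mitosis_count": ((5.17, 1.88), (6.93, 4.55)),
    "ki67": ((5.05, 2.20), (10.21, 7.06)),
}
TABLE_BINARY: dict[str, tuple[float, float]] = {
    "female": (21 / 41, 4 / 7),
    "recurrent": (3 / 41, 1 / 7),
    "skull_base": (3 / 41, 1 / 7),
    "heterogeneous_enhancement": (19 / 41, 6 / 7),
    "capsular_enhancement": (5 / 41, 0.0),
    "necrosis": (14 / 41, 2 / 7),
    "cystic_change": (8 / 41, 1 / 7),
    "hyperostosis": (10 / 41, 3 / 7),
    "skull_invasion": (7 / 41, 3 / 7),
}

#: feature domains enforced by redraw-truncation
_BOUNDS = {
    "fd": (1.0, 3.0),
    "lacunarity": (1e-9, np.inf),
    "age": (0.0, np.inf),
    "max_diameter_cm": (1e-9, np.inf),
    "mitosis_count": (0.0, np.inf),
    "ki67": (0.0, np.inf),
}


#: published two-feature logistic model for mutation status,
#: ln(p/(1−p)) = −1.768 + 3.482·FD + 3.022·lacunarity. At the raw feature
#: scale (FD ≈ 1.8, lacunarity ≈ 5.5) this linear predictor is ≈ +21 — a
#: probability of 1 for every subject — whereas the intercept alone gives
#: logistic(−1.768) = 0.146, exactly the 7/48 mutant prevalence of the source
#: cohort. The equation is therefore interpreted as acting on mean-centred
#: covariates, which is also how it is used as simulation ground truth.
TWO_FEATURE_MODEL: dict[str, float] = {"const": -1.768, "fd": 3.482, "lacunarity": 3.022}


def simulate_logit_cohort(
    n: int,
    coefficients: Mapping[str, float] | None = None,
    covariate_sd: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate (centred fd, centred lacunarity, outcome) from a logistic model.

    Covariates are independent centred Gaussians with SD ``covariate_sd``
    (default 0.5: enough spread that a maximum-likelihood refit at n of a few
    thousand pins each coefficient to a few percent, while the intercept keeps
    the event rate near the source cohort's 0.15). Used for parameter-recovery
    experiments against :data:`TWO_FEATURE_MODEL`.
    """
    if n < 10:
        raise ParameterError("n must be at least 10")
    coefficients = dict(coefficients or TWO_FEATURE_MODEL)
    rng = np.random.default_rng(seed)
    fd = rng.normal(0.0, covariate_sd, n)
    lac = rng.normal(0.0, covariate_sd, n)
    eta = coefficients["const"] + coefficients["fd"] * fd + coefficients["lacunarity"] * lac
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
    return pd.DataFrame({"fd": fd, "lacunarity": lac, "outcome": y})


def make_primitive(kind: str, side_or_radius: int, spacing: float = 1.0) -> VoxelMask:
    """Exact digital primitive: cube (s³), slab (s×s×1), line (s×1×1) or ball.

    The ball keeps voxels whose centre lies within ``radius`` of the central
    voxel centre, on a (2r+1)³ grid.
    """
    s = int(side_or_radius)
    if s < 1:
        raise ParameterError(f"size must be a positive integer, got {side_or_radius}")
    if kind == "cube":
        grid = np.ones((s, s, s), dtype=np.uint8)
    elif kind == "slab":
        grid = np.ones((s, s, 1), dtype=np.uint8)
    elif kind == "line":
        grid = np.ones((s, 1, 1), dtype=np.uint8)
    elif kind == "ball":
        grid = _ball_grid(s)
    else:
        raise ParameterError(f"unknown primitive kind {kind!r}")
    return VoxelMask(grid=grid, spacing=(spacing,) * 3, subject_id=f"{kind}_{s}")


def _ball_grid(radius: int) -> np.ndarray:
    n = 2 * radius + 1
    c = np.arange(n) - radius
    d2 = c[:, None, None] ** 2 + c[None, :, None] ** 2 + c[None, None, :] ** 2
    return (d2 <= radius**2).astype(np.uint8)


def make_menger_sponge(level: int, spacing: float = 1.0) -> VoxelMask:
    """Level-``level`` Menger sponge on a 3^level grid (20^level voxels).

    Recursive construction: of each 3×3×3 block of sub-cubes, the 6 face
    centres and the body centre are removed, keeping 20. Its box dimension is
    log20/log3 ≈ 2.7268, with exact triadic counts N(3^j) = 20^(level−j).
    """
    if not 1 <= int(level) <= 5:
        raise ParameterError(f"level must be in 1..5 (3^level grid), got {level}")
    coords = np.arange(3)
    centre_like = (
        (coords[:, None, None] == 1).astype(int)
        + (coords[None, :, None] == 1)
        + (coords[None, None, :] == 1)
    )
    pattern = (centre_like <= 1).astype(np.uint8)  # 20 of 27 kept
    grid = np.ones((1, 1, 1), dtype=np.uint8)
    for _ in range(int(level)):
        grid = np.kron(grid, pattern)
    return VoxelMask(grid=grid, spacing=(spacing,) * 3, subject_id=f"menger_{level}")


def make_blob(
    radius_mm: float = 20.0,
    irregularity: float = 0.3,
    gap_fraction: float = 0.0,
    gap_size_vox: int = 3,
    seed: int = 0,
    spacing: float = 1.0,
) -> VoxelMask:
    """Tumour-like phantom: a noise-perturbed ball with optional internal gaps.

    The boundary is the level set ``|x−c| ≤ R(1 + a·n(x))`` where n is a
    smooth unit-amplitude random field and ``a = 0.6·irregularity``, so
    irregularity 0 degenerates to a plain digital ball. Gaps are spherical
    holes of radius ``gap_size_vox`` carved at random interior voxels until
    about ``gap_fraction`` of the initial volume is removed; the largest
    6-connected component is kept, so the phantom is always connected.
    Deterministic for a fixed seed.
    """
    if not 0 <= irregularity <= 1:
        raise ParameterError(f"irregularity must be in [0,1], got {irregularity}")
    if not 0 <= gap_fraction < 0.95:
        raise ParameterError(f"gap_fraction must be in [0, 0.95), got {gap_fraction}")
    if radius_mm <= 0 or gap_size_vox < 1:
        raise ParameterError("radius_mm must be positive and gap_size_vox >= 1")
    rng = np.random.default_rng(seed)
    r_vox = radius_mm / spacing
    amp = 0.2 * irregularity
    half = int(np.ceil(r_vox * (1 + 2.5 * amp))) + 2
    n = 2 * half + 1
    c = np.arange(n) - half
    dist = np.sqrt(c[:, None, None] ** 2 + c[None, :, None] ** 2 + c[None, None, :] ** 2)
    if irregularity > 0:
        # multi-octave surface roughness: white noise at mid-to-fine grids
        # upsampled with cubic splines and summed with 0.7 persistence. Only
        # wavelengths well below the object diameter are included — coarse
        # octaves merely deform the gross shape without changing the measured
        # box-counting slope, while fine octaves roughen the border across
        # the scales the counting ladder probes.
        field = np.zeros((n, n, n))
        weight = 1.0
        for res in (16, 32, 64):
            low = rng.standard_normal((res,) * 3)
            field += weight * ndimage.zoom(low, [n / res] * 3, order=3)[:n, :n, :n]
            weight *= 0.7
        field = np.clip(field / field.std(), -2.5, 2.5)
    else:
        field = np.zeros((n, n, n))
    grid = (dist <= r_vox * (1.0 + amp * field)).astype(np.uint8)

    if gap_fraction > 0:
        initial = int(grid.sum())
        target_removed = gap_fraction * initial
        removed = 0
        g = int(gap_size_vox)
        gc = np.arange(2 * g + 1) - g
        gd2 = gc[:, None, None] ** 2 + gc[None, :, None] ** 2 + gc[None, None, :] ** 2
        hole = gd2 <= g**2
        fg = np.argwhere(grid)
        order = rng.permutation(len(fg))
        for idx in order:
            if removed >= target_removed:
                break
            z, y, x = fg[idx]
            zl, yl, xl = max(z - g, 0), max(y - g, 0), max(x - g, 0)
            zh, yh, xh = min(z + g + 1, n), min(y + g + 1, n), min(x + g + 1, n)
            sub = grid[zl:zh, yl:yh, xl:xh]
            hsub = hole[zl - (z - g) : (2 * g + 1) - ((z + g + 1) - zh),
                        yl - (y - g) : (2 * g + 1) - ((y + g + 1) - yh),
                        xl - (x - g) : (2 * g + 1) - ((x + g + 1) - xh)]
            removed += int((sub & hsub).sum())
            sub[hsub] = 0
        labels, n_comp = ndimage.label(grid)
        if n_comp > 1:
            sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n_comp + 1))
            grid = (labels == (1 + int(np.argmax(sizes)))).astype(np.uint8)
    if grid.sum() == 0:
        raise ParameterError("blob parameters produced an empty mask")
    return VoxelMask(grid=grid, spacing=(spacing,) * 3, subject_id=f"blob_s{seed}")


@dataclasses.dataclass
class CohortSpec:
    """Parameters of a synthetic two-group cohort.

    Exactly one of ``n_per_group`` or (``n_total``, ``prevalence``) sizes the
    cohort; with the latter the mutant count is ``round(n_total·prevalence)``.
    ``continuous`` maps variable → ((mean, sd) wildtype, (mean, sd) mutant);
    ``binary`` maps variable → (p wildtype, p mutant). ``fd_lacunarity_corr``
    is the within-group correlation of the two fractal features (default 0:
    only marginals are published). FD draws are truncated to [1, 3] and
    lacunarity to (0, ∞) by redrawing.
    """

    n_total: int | None = 48
    prevalence: float = 7 / 48
    n_per_group: Mapping[str, int] | None = None
    continuous: Mapping[str, tuple[tuple[float, float], tuple[float, float]]] = dataclasses.field(
        default_factory=lambda: dict(TABLE_CONTINUOUS)
    )
    binary: Mapping[str, tuple[float, float]] = dataclasses.field(
        default_factory=lambda: dict(TABLE_BINARY)
    )
    include_pathology: bool = True
    fd_lacunarity_corr: float = 0.0
    seed: int = 0

    def group_sizes(self) -> dict[str, int]:
        if self.n_per_group is not None:
            sizes = {g: int(n) for g, n in self.n_per_group.items()}
        else:
            if self.n_total is None or self.n_total < 2:
                raise ParameterError("n_total must be >= 2")
            if not 0 < self.prevalence < 1:
                raise ParameterError(f"prevalence must be in (0,1), got {self.prevalence}")
            n_mut = int(round(self.n_total * self.prevalence))
            sizes = {"wildtype": int(self.n_total) - n_mut, "mutant": n_mut}
        if any(n < 1 for n in sizes.values()):
            raise ParameterError(f"each group needs >= 1 subject, got {sizes}")
        for var, ((_, s0), (_, s1)) in self.continuous.items():
            if s0 <= 0 or s1 <= 0:
                raise ParameterError(f"SD for {var} must be positive")
        for var, (p0, p1) in self.binary.items():
            if not (0 <= p0 <= 1 and 0 <= p1 <= 1):
                raise ParameterError(f"proportions for {var} must be in [0,1]")
        if not -1 < self.fd_lacunarity_corr < 1:
            raise ParameterError("fd_lacunarity_corr must be in (-1, 1)")
        return sizes


def _draw_truncated(rng, mean, sd, low, high, size):
    x = rng.normal(mean, sd, size)
    for _ in range(1000):
        bad = (x < low) | (x > high)
        if not bad.any():
            return x
        x[bad] = rng.normal(mean, sd, int(bad.sum()))
    raise ParameterError(f"truncation bounds ({low}, {high}) infeasible for N({mean}, {sd})")


def _draw_fd_lac(rng, fd_ms, lac_ms, corr, size):
    """Jointly truncated bivariate-normal (fd, lacunarity) draws."""
    cov = np.array(
        [
            [fd_ms[1] ** 2, corr * fd_ms[1] * lac_ms[1]],
            [corr * fd_ms[1] * lac_ms[1], lac_ms[1] ** 2],
        ]
    )
    mean = np.array([fd_ms[0], lac_ms[0]])
    x = rng.multivariate_normal(mean, cov, size=size, method="cholesky")
    for _ in range(1000):
        bad = (
            (x[:, 0] < _BOUNDS["fd"][0])
            | (x[:, 0] > _BOUNDS["fd"][1])
            | (x[:, 1] < _BOUNDS["lacunarity"][0])
        )
        if not bad.any():
            return x[:, 0], x[:, 1]
        x[bad] = rng.multivariate_normal(mean, cov, size=int(bad.sum()), method="cholesky")
    raise ParameterError("fd/lacunarity truncation failed to converge")


def generate_cohort(spec: CohortSpec | None = None, **overrides) -> pd.DataFrame:
    """Simulate a two-group cohort table.

    Continuous variables are per-group Gaussian (fd and lacunarity jointly,
    with the configured within-group correlation); binary findings are
    per-group Bernoulli; defaults reproduce the published group summaries.
    Rows are ordered wildtype-first with sequential ids; the same spec and
    seed always give a bit-identical table.
    """
    if spec is None:
        spec = CohortSpec(**overrides)
    elif overrides:
        spec = dataclasses.replace(spec, **overrides)
    sizes = spec.group_sizes()
    rng = np.random.default_rng(spec.seed)
    frames = []
    for gi, (group, n) in enumerate(sorted(sizes.items(), reverse=True)):  # wildtype first
        cols: dict[str, np.ndarray] = {}
        cont = dict(spec.continuous)
        if spec.include_pathology:
            cont.update(TABLE_PATHOLOGY)
        fd_ms = cont.pop("fd", None)
        lac_ms = cont.pop("lacunarity", None)
        for var, ms in cont.items():
            m, s = ms[0] if group == "wildtype" else ms[1]
            low, high = _BOUNDS.get(var, (-np.inf, np.inf))
            cols[var] = _draw_truncated(rng, m, s, low, high, n)
        if fd_ms is not None and lac_ms is not None:
            j = 0 if group == "wildtype" else 1
            cols["fd"], cols["lacunarity"] = _draw_fd_lac(
                rng, fd_ms[j], lac_ms[j], spec.fd_lacunarity_corr, n
            )
        for var, (p0, p1) in spec.binary.items():
            p = p0 if group == "wildtype" else p1
            cols[var] = (rng.random(n) < p).astype(int)
        df = pd.DataFrame(cols)
        df.insert(0, "group", group)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "subject_id", [f"S{i + 1:04d}" for i in range(len(out))])
    if "female" in out.columns:
        out.insert(out.columns.get_loc("female"), "sex",
                   np.where(out.pop("female") == 1, "female", "male"))
    ordered = [c for c in (
        "subject_id", "group", "age", "sex", "recurrent", "skull_base",
        "heterogeneous_enhancement", "capsular_enhancement", "necrosis",
        "cystic_change", "hyperostosis", "skull_invasion", "max_diameter_cm",
        "fd", "lacunarity", "mitosis_count", "ki67",
    ) if c in out.columns]
    return out[ordered + [c for c in out.columns if c not in ordered]]
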