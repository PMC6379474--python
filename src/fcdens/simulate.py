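"""Synthetic two-group resting-state BOLD datasets with known connectivity.

The generator builds datasets that exercise every downstream stage of the
connectivity-density pipeline without any acquisition: two groups of subjects
on a shared gray-matter mask, with designated *hubs* — sets of voxels that
share a latent signal so that their mutual Pearson correlation has a known
expectation — split into short-range hubs (all member pairs within the 6 mm
neighborhood radius) and long-range hubs (all member pairs beyond it).

Signal model.  Every voxel time series is a unit-variance AR(1) process.
A hub member mixes a hub-wide latent ``s_h`` with private noise ``e_v``::

    x_v(t) = sqrt(rho) * s_h(t) + sqrt(1 - rho) * e_v(t)

with ``s_h`` and ``e_v`` independent and unit variance, so the expected
pairwise correlation between two members is exactly ``rho`` (exact when the
spatial noise correlation below is disabled).  Group effects multiply the
shared-signal weight in the patient group: with multiplier ``m``, the
patient-group expected correlation is ``rho * m**2`` (a multiplier < 1
models a connectivity-density deficit, > 1 an increase).  Non-hub voxels
carry noise only.  All series are generated at unit variance before
scaling, so degree differences downstream reflect correlation structure
only.

Spatial structure.  Real BOLD volumes are spatially smooth, which gives
every gray-matter voxel a nonzero short-range degree; without it the
background degree maps would be almost everywhere zero and mean-scaling
would degenerate.  The noise fields are therefore smoothed with a small
Gaussian kernel (``spatial_noise_fwhm_mm``, default 3 mm) before the
temporal AR(1) recursion, inducing a neighbor correlation of roughly
``exp(-d^2 / (4 sigma^2))`` (~0.25 at one 3 mm voxel step) that decays to
~0 beyond the 6 mm neighborhood.
Set it to 0 for exactly independent noise (used when verifying the mixing
identity).  For short hubs the smoothing slightly inflates the within-hub
correlation above ``rho``, since member private noise becomes correlated.

Clinical covariates are generated as linear functions of each subject's
hub coupling strength plus Gaussian noise, scaled so the population
correlation equals a designed ``target_r``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .volumes import BoldSeries, GrayMatterMask, VolumeGrid

__all__ = [
    "ConfigurationError",
    "HubSpec",
    "EffectSpec",
    "ClinicalSpec",
    "SimulationConfig",
    "generate_dataset",
    "make_clinical_table",
    "default_mask",
    "reference_config",
    "ground_truth_region",
]

#: Neighborhood radius (mm) separating short- from long-range connections.
SHORT_RANGE_RADIUS_MM = 6.0


class ConfigurationError(ValueError):
    """A simulation configuration violates its invariants."""


@dataclass(frozen=True)
class HubSpec:
    """A set of voxels sharing a latent signal.

    ``range_class`` declares whether all member pairs lie within
    (``"short"``) or beyond (``"long"``) the 6 mm neighborhood radius;
    this is validated against the actual geometry at generation time.
    """

    member_voxels: tuple[tuple[int, int, int], ...]
    coupling_rho: float
    range_class: str  # "short" | "long"

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "member_voxels",
            tuple(tuple(int(c) for c in v) for v in self.member_voxels),
        )
        if not 0 < self.coupling_rho < 1:
            raise ConfigurationError(
                f"coupling_rho must be in (0, 1), got {self.coupling_rho}"
            )
        if self.range_class not in ("short", "long"):
            raise ConfigurationError(
                f"range_class must be 'short' or 'long', got {self.range_class!r}"
            )
        if len(self.member_voxels) < 2:
            raise ConfigurationError("a hub needs at least 2 member voxels")

    def validate_geometry(self, grid: VolumeGrid, radius_mm: float = SHORT_RANGE_RADIUS_MM):
        """Check that member pair distances honor the declared range class."""
        pts = grid.voxel_to_world(np.asarray(self.member_voxels))
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        iu = np.triu_indices(len(pts), k=1)
        pair_d = d[iu]
        if self.range_class == "short" and np.any(pair_d > radius_mm + 1e-9):
            raise ConfigurationError(
                f"short hub has member pair {pair_d.max():.2f} mm apart "
                f"(> {radius_mm} mm)"
            )
        if self.range_class == "long" and np.any(pair_d <= radius_mm + 1e-9):
            raise ConfigurationError(
                f"long hub has member pair {pair_d.min():.2f} mm apart "
                f"(<= {radius_mm} mm)"
            )

    def mask(self, grid: VolumeGrid) -> np.ndarray:
        m = np.zeros(grid.dims, dtype=bool)
        for v in self.member_voxels:
            m[v] = True
        return m


@dataclass(frozen=True)
class EffectSpec:
    """Group effect: multiply one hub's shared-signal weight in patients."""

    hub_index: int
    group_multiplier: float

    def __post_init__(self) -> None:
        if self.group_multiplier < 0:
            raise ConfigurationError("group_multiplier must be >= 0")


@dataclass(frozen=True)
class ClinicalSpec:
    """A clinical variable with a designed correlation to hub coupling.

    The variable is generated with population mean ``mean``, standard
    deviation ``sd``, and population Pearson correlation ``target_r`` with
    the subject-level coupling strength of hub ``hub_index``.
    """

    name: str
    hub_index: int
    target_r: float
    mean: float = 0.0
    sd: float = 1.0

    def __post_init__(self) -> None:
        if not -1.0 <= self.target_r <= 1.0:
            raise ConfigurationError(f"|target_r| must be <= 1, got {self.target_r}")
        if self.sd <= 0:
            raise ConfigurationError("sd must be positive")


@dataclass
class SimulationConfig:
    """Full description of a synthetic two-group dataset.

    Defaults mirror a typical 3 T resting-state acquisition after discarding
    initial volumes: 24 subjects per group, 230 volumes at TR = 3 s on a
    3 mm isotropic grid.
    """

    n_per_group: int = 24
    grid_dims: tuple[int, int, int] = (16, 16, 16)
    voxel_size_mm: float = 3.0
    n_volumes: int = 230
    tr_s: float = 3.0
    mask_fraction: float = 0.7
    hubs: list[HubSpec] = field(default_factory=list)
    group_effects: list[EffectSpec] = field(default_factory=list)
    clinical_specs: list[ClinicalSpec] = field(default_factory=list)
    noise_sd: float = 1.0
    temporal_ar1: float = 0.3
    spatial_noise_fwhm_mm: float = 3.0
    coupling_jitter_sd: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ConfigurationError("n_per_group must be >= 1")
        if self.n_volumes < 20:
            raise ConfigurationError("n_volumes must be >= 20")
        if any(d < 6 for d in self.grid_dims):
            raise ConfigurationError("grid_dims must each be >= 6")
        if not 0 < self.mask_fraction <= 1:
            raise ConfigurationError("mask_fraction must be in (0, 1]")
        if self.voxel_size_mm <= 0 or self.tr_s <= 0 or self.noise_sd <= 0:
            raise ConfigurationError("voxel_size_mm, tr_s, noise_sd must be > 0")
        if not 0 <= self.temporal_ar1 < 1:
            raise ConfigurationError("temporal_ar1 must be in [0, 1)")
        if self.spatial_noise_fwhm_mm < 0:
            raise ConfigurationError("spatial_noise_fwhm_mm must be >= 0")
        for eff in self.group_effects:
            if not 0 <= eff.hub_index < len(self.hubs):
                raise ConfigurationError(f"effect refers to missing hub {eff.hub_index}")
            rho_eff = self.patient_rho(eff.hub_index)
            if rho_eff >= 1:
                raise ConfigurationError(
                    f"patient-group rho {rho_eff:.3f} for hub {eff.hub_index} "
                    "is outside [0, 1)"
                )
        for cs in self.clinical_specs:
            if not 0 <= cs.hub_index < len(self.hubs):
                raise ConfigurationError(
                    f"clinical spec {cs.name!r} refers to missing hub {cs.hub_index}"
                )

    @property
    def grid(self) -> VolumeGrid:
        s = float(self.voxel_size_mm)
        return VolumeGrid(tuple(self.grid_dims), (s, s, s))

    def patient_rho(self, hub_index: int) -> float:
        """Expected within-hub correlation in the patient group."""
        rho = self.hubs[hub_index].coupling_rho
        for eff in self.group_effects:
            if eff.hub_index == hub_index:
                rho = rho * eff.group_multiplier**2
        return rho

    def control_rho(self, hub_index: int) -> float:
        return self.hubs[hub_index].coupling_rho


def default_mask(config: SimulationConfig) -> GrayMatterMask:
    """Centered cuboid covering ~``mask_fraction`` of the grid.

    A compact convex mask keeps cluster topology simple and makes hub
    placement predictable; it stands in for a gray-matter mask.
    """
    dims = np.asarray(config.grid_dims)
    frac = config.mask_fraction ** (1.0 / 3.0)
    ext = np.maximum(np.rint(dims * frac).astype(int), 1)
    lo = (dims - ext) // 2
    m = np.zeros(tuple(dims), dtype=bool)
    m[lo[0]:lo[0] + ext[0], lo[1]:lo[1] + ext[1], lo[2]:lo[2] + ext[2]] = True
    return GrayMatterMask(grid=config.grid, membership=m)


def _ar1_filter(e: np.ndarray, phi: float) -> np.ndarray:
    """Stationary unit-variance AR(1) recursion over axis 0 of unit-variance
    innovations."""
    if phi == 0:
        return e
    x = np.empty_like(e)
    x[0] = e[0]
    c = np.sqrt(1.0 - phi**2)
    for t in range(1, e.shape[0]):
        x[t] = phi * x[t - 1] + c * e[t]
    return x


def _ar1(rng: np.random.Generator, n_t: int, n_series: int, phi: float) -> np.ndarray:
    """Independent stationary unit-variance AR(1) series, (n_t, n_series)."""
    return _ar1_filter(rng.standard_normal((n_t, n_series)), phi)


def _noise_fields(
    rng: np.random.Generator,
    n_t: int,
    mask: GrayMatterMask,
    phi: float,
    spatial_fwhm_mm: float,
) -> np.ndarray:
    """Spatially smooth AR(1) noise over the mask, (n_t, n_mask), unit
    sample variance per voxel."""
    if spatial_fwhm_mm == 0:
        return _ar1(rng, n_t, mask.n_voxels, phi)
    from scipy.ndimage import gaussian_filter

    vs = np.asarray(mask.grid.voxel_size_mm)
    sigma_vox = spatial_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / vs
    white = rng.standard_normal((n_t,) + mask.grid.dims)
    smooth = gaussian_filter(white, sigma=(0.0, *sigma_vox), mode="constant")
    e = smooth[:, mask.membership]
    e = (e - e.mean(axis=0)) / e.std(axis=0)
    return _ar1_filter(e, phi)


def _subject_couplings(
    config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """(n_subjects, n_hubs) per-subject coupling strengths.

    Controls come first.  Each subject's coupling is the group-level rho
    plus a small truncated Gaussian jitter, giving the between-subject
    variability that clinical correlations hook into.
    """
    n_sub = 2 * config.n_per_group
    n_hub = len(config.hubs)
    c = np.empty((n_sub, n_hub))
    for h in range(n_hub):
        base = np.r_[
            np.full(config.n_per_group, config.control_rho(h)),
            np.full(config.n_per_group, config.patient_rho(h)),
        ]
        jit = rng.normal(0.0, config.coupling_jitter_sd, size=n_sub)
        c[:, h] = np.clip(base + jit, 0.0, 1.0 - 1e-6)
    return c


def generate_dataset(
    config: SimulationConfig,
    mask: GrayMatterMask | None = None,
) -> tuple[list[BoldSeries], pd.DataFrame, list[np.ndarray]]:
    """Simulate all subjects of a two-group study.

    Returns
    -------
    bold_list : list of BoldSeries
        ``2 * n_per_group`` runs, controls first then patients, on a
        shared grid.  Reproducible bit-for-bit given ``config.seed``.
    table : pandas.DataFrame
        Subject table with group labels, age/education and clinical
        variables (see :func:`make_clinical_table`).
    hub_masks : list of 3-D bool arrays
        Ground-truth member mask per hub.
    """
    grid = config.grid
    if mask is None:
        mask = default_mask(config)
    elif mask.grid.dims != grid.dims:
        raise ConfigurationError("supplied mask grid does not match config grid")

    for hub in config.hubs:
        hub.validate_geometry(grid)
        for v in hub.member_voxels:
            if not mask.membership[v]:
                raise ConfigurationError(f"hub voxel {v} lies outside the mask")
    members_flat = [v for hub in config.hubs for v in hub.member_voxels]
    if len(set(members_flat)) != len(members_flat):
        raise ConfigurationError("hubs must not share member voxels")

    rng = np.random.default_rng(config.seed)
    couplings = _subject_couplings(config, rng)

    vox_idx = mask.voxel_indices()
    flat_of_voxel = {tuple(v): i for i, v in enumerate(vox_idx)}
    n_sub = 2 * config.n_per_group

    bold_list: list[BoldSeries] = []
    for i in range(n_sub):
        series = _noise_fields(
            rng, config.n_volumes, mask, config.temporal_ar1,
            config.spatial_noise_fwhm_mm,
        )
        noise = series
        for h, hub in enumerate(config.hubs):
            latent = _ar1(rng, config.n_volumes, 1, config.temporal_ar1)[:, 0]
            rho = couplings[i, h]
            w_s, w_n = np.sqrt(rho), np.sqrt(1.0 - rho)
            for v in hub.member_voxels:
                j = flat_of_voxel[v]
                series[:, j] = w_s * latent + w_n * noise[:, j]
        data = np.zeros(grid.dims + (config.n_volumes,))
        data[mask.membership] = (config.noise_sd * series).T
        sid = f"sub-{i + 1:02d}"
        bold_list.append(
            BoldSeries(grid=grid, data=data, tr_s=config.tr_s, subject_id=sid)
        )

    table = make_clinical_table(config, couplings, rng)
    hub_masks = [hub.mask(grid) for hub in config.hubs]
    return bold_list, table, hub_masks


def make_clinical_table(
    config: SimulationConfig,
    couplings: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Subject table with designed clinical-variable correlations.

    Each :class:`ClinicalSpec` variable is ``mean + sd * y`` with
    ``y = r * z + sqrt(1 - r^2) * e`` where ``z`` is the coupling strength
    of the referenced hub standardized *within each group* and ``e``
    independent standard normal, so the within-group population correlation
    with coupling equals ``target_r`` (and the sample correlation is exact
    when ``|target_r| = 1``).  Standardizing within group keeps the design
    meaningful for correlation analyses run inside the patient group, which
    would otherwise be swamped by the between-group coupling gap.  Age and
    education are drawn group-matched (same distribution for both groups).
    """
    n_sub = couplings.shape[0] if couplings.ndim else 0
    if n_sub != 2 * config.n_per_group:
        raise ConfigurationError(
            f"expected {2 * config.n_per_group} coupling rows, got {n_sub}"
        )
    n = config.n_per_group
    table = pd.DataFrame(
        {
            "subject_id": [f"sub-{i + 1:02d}" for i in range(n_sub)],
            "group": ["control"] * n + ["patient"] * n,
            # group-matched demographics, middle-aged male cohort scale
            "age": np.round(rng.normal(47.75, 6.95, size=n_sub), 1),
            "education": np.round(np.clip(rng.normal(9.0, 3.15, size=n_sub), 0, None), 1),
        }
    )
    group = np.asarray(["control"] * n + ["patient"] * n)
    for cs in config.clinical_specs:
        c = couplings[:, cs.hub_index]
        z = np.zeros(n_sub)
        for g in ("control", "patient"):
            sel = group == g
            sd_c = c[sel].std()
            if sd_c > 0:
                z[sel] = (c[sel] - c[sel].mean()) / sd_c
        r = cs.target_r
        e = rng.standard_normal(n_sub)
        y = r * z + np.sqrt(max(0.0, 1.0 - r**2)) * e
        table[cs.name] = cs.mean + cs.sd * y
    return table


def reference_config(
    n_per_group: int = 6,
    grid_size: int = 12,
    n_volumes: int = 150,
    seed: int = 0,
    effects: bool = True,
) -> SimulationConfig:
    """Reference two-hub study configuration used for recovery benchmarks.

    Injects one short-range hub (a 7-voxel face-adjacent "plus", all member
    pairs within 6 mm) whose coupling is *increased* in patients
    (0.05 -> 0.80), and one long-range hub (8 voxels at the corners of a
    9 mm cube, all pairs > 6 mm apart) whose coupling is *decreased*
    (0.81 -> 0.073).  Hub positions are derived from the mask bounds so the
    same recipe scales from the 12^3 desk grid to larger grids.  With
    ``effects=False`` both multipliers are 1, giving a null dataset for
    false-positive calibration.

    The desk defaults (6 + 6 subjects, 12^3 grid, 150 volumes) trade sample
    size for speed while keeping both effects comfortably recoverable; the
    full-scale variant is ``reference_config(24, 16, 230)``.
    """
    cfg_probe = SimulationConfig(
        n_per_group=n_per_group,
        grid_dims=(grid_size,) * 3,
        n_volumes=n_volumes,
        seed=seed,
    )
    m = default_mask(cfg_probe).membership
    occ = np.argwhere(m)
    lo, hi = occ.min(axis=0), occ.max(axis=0)
    ext = hi - lo + 1

    c = tuple(lo + np.maximum(ext // 3, 1))
    plus = [c] + [
        (c[0] + dx, c[1] + dy, c[2] + dz)
        for dx, dy, dz in
        [(-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1)]
    ]
    base = lo + ext // 2
    corners = [
        tuple(base + np.array([dx, dy, dz]) * 3)
        for dx in (0, 1) for dy in (0, 1) for dz in (0, 1)
    ]
    hubs = [
        HubSpec(tuple(plus), coupling_rho=0.05, range_class="short"),
        HubSpec(tuple(corners), coupling_rho=0.81, range_class="long"),
    ]
    mult_short, mult_long = (4.0, 0.3) if effects else (1.0, 1.0)
    return SimulationConfig(
        n_per_group=n_per_group,
        grid_dims=(grid_size,) * 3,
        n_volumes=n_volumes,
        hubs=hubs,
        group_effects=[
            EffectSpec(hub_index=0, group_multiplier=mult_short),
            EffectSpec(hub_index=1, group_multiplier=mult_long),
        ],
        clinical_specs=[
            ClinicalSpec("years_of_drinking", hub_index=1, target_r=-0.6,
                         mean=27.46, sd=10.89),
            ClinicalSpec("SADQ", hub_index=0, target_r=0.5, mean=20.21, sd=7.09),
            ClinicalSpec("AUDIT", hub_index=0, target_r=0.3, mean=24.08, sd=5.69),
            ClinicalSpec("daily_consumption", hub_index=1, target_r=0.0,
                         mean=237.5, sd=115.39),
        ],
        seed=seed,
    )


def ground_truth_region(
    hub_mask: np.ndarray, grid: VolumeGrid, dilate_mm: float = 6.0
) -> np.ndarray:
    """Spatial footprint a hub effect occupies in the smoothed maps.

    The member mask is dilated by ``dilate_mm`` (default: the 6 mm map
    smoothing FWHM), the support over which the Gaussian kernel spreads a
    clearly detectable injected effect; recovered clusters are scored
    against this footprint by Dice overlap.
    """
    from scipy.ndimage import binary_dilation, generate_binary_structure

    n_it = int(np.floor(dilate_mm / min(grid.voxel_size_mm) + 1e-9))
    if n_it < 1:
        return hub_mask.copy()
    struct = generate_binary_structure(3, 1)
    return binary_dilation(hub_mask, structure=struct, iterations=n_it)
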