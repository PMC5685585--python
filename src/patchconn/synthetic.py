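"""Reproducible synthetic cohorts with known group structure.

Two branches share one truth/label schema so downstream code is agnostic to
provenance:

* **volumes** — a smooth "anatomy" template inside an ellipsoidal brain
  mask; each subject is the template plus a smooth subject-specific
  deformation field plus i.i.d. voxel noise. "Atrophy" in designated case
  groups is injected at patch granularity as intensity attenuation toward
  the mask-interior mean plus partial replacement by independent noise
  (decorrelation) — the two modes patch-correlation connectivity actually
  responds to.
* **matrices** — a direct generator of n x N x N connectivity cohorts. Each
  node carries a latent feature vector (shared low-rank factor structure
  plus i.i.d. per-subject noise) and the subject's network is the empirical
  Pearson correlation matrix of those vectors, so every matrix is symmetric
  with unit diagonal by construction. For case subjects, affected nodes'
  vectors are mixed with independent noise in proportion to the effect
  size, which alters their connectivity pattern and shrinks |c_ij|.

All randomness flows from a single master seed through
``numpy.random.SeedSequence.spawn`` (one child stream per subject), so
identical configurations reproduce bitwise-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from patchconn._util import as_seed_sequence
from patchconn.errors import DesignError, ParameterError, SizingError
from patchconn.network import PatchGrid, Patch, build_patch_grid

#: Group sizes of the four-arm case-control study design the defaults
#: emulate (healthy controls, MCI non-converters, MCI converters, AD).
REFERENCE_GROUP_SIZES = {"HC": 80, "ncMCI": 82, "cMCI": 70, "AD": 84}

#: Smoothing (voxels) of the per-subject deformation field.
_SUBJECT_FIELD_SIGMA = 3.0


@dataclass(frozen=True)
class RegionEffect:
    """Atrophy-like perturbation of one patch region.

    ``attenuation`` pulls intensities toward the mask-interior mean;
    ``decorrelation`` is the fraction of the signal replaced by independent
    noise with matched mean/spread. Both in [0, 1].
    """

    patch: Patch
    attenuation: float = 0.0
    decorrelation: float = 0.0

    def __post_init__(self):
        for name in ("attenuation", "decorrelation"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1], got {v}")


@dataclass
class CohortConfig:
    """Parameters of a synthetic volumetric cohort."""

    volume_shape: tuple[int, int, int] = (40, 45, 40)
    patch_dims: tuple[int, int, int] = (10, 15, 20)
    group_sizes: dict = field(
        default_factory=lambda: {"control": 10, "case": 10}
    )
    affected_nodes: frozenset = frozenset()
    effect_size: float = 0.0
    subject_noise_sd: float = 2.0
    voxel_noise_sd: float = 1.0
    seed: int = 0
    # atrophy mode weights; the effective perturbation of an affected patch
    # is (effect_size * attenuation, effect_size * decorrelation)
    attenuation: float = 0.8
    decorrelation: float = 0.8
    retention_threshold: float = 0.5
    case_groups: tuple | None = None  # default: every group after the first

    def validate(self) -> None:
        if sum(self.group_sizes.values()) < 4:
            raise DesignError("cohort needs at least 4 subjects in total")
        if any(n < 1 for n in self.group_sizes.values()):
            raise DesignError("every group needs at least 1 subject")
        if self.effect_size < 0:
            raise ParameterError("effect_size must be non-negative")
        if self.subject_noise_sd <= 0 or self.voxel_noise_sd <= 0:
            raise ParameterError("noise SDs must be positive")
        for v in (self.effect_size * self.attenuation,
                  self.effect_size * self.decorrelation):
            if not 0.0 <= v <= 1.0:
                raise ParameterError(
                    "effect_size * attenuation/decorrelation must land in [0, 1]"
                )


@dataclass
class SyntheticCohort:
    """A generated cohort: subjects, labels, and the ground-truth node set."""

    subject_ids: list[str]
    labels: list[str]
    truth: frozenset
    provenance: dict
    volumes: list | None = None
    mask: np.ndarray | None = None
    grid: PatchGrid | None = None
    matrices: np.ndarray | None = None  # (n, N, N)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def connectivity(self) -> np.ndarray:
        """The cohort's connectivity stack, computing it from volumes if needed."""
        if self.matrices is not None:
            return self.matrices
        from patchconn.network import compute_connectivity

        return np.stack([
            compute_connectivity(v, self.grid, subject_id=sid).values
            for v, sid in zip(self.volumes, self.subject_ids)
        ])


def generate_template(volume_shape, seed=None) -> tuple[np.ndarray, np.ndarray]:
    """A smooth positive intensity field inside an ellipsoidal brain mask.

    The field is a superposition of low-frequency cosine modes with seeded
    random amplitudes and phases; the mask is a fixed ellipsoid (independent
    of the seed) symmetric about the midsagittal plane within one voxel.
    """
    shape = tuple(int(s) for s in volume_shape)
    if len(shape) != 3 or min(shape) < 4:
        raise SizingError(
            f"volume_shape must be 3 ints, each >= 4 voxels; got {volume_shape}"
        )
    rng = np.random.default_rng(seed)
    # normalized coordinates in [-1, 1], symmetric about the volume center
    axes = [
        (np.arange(s) - (s - 1) / 2.0) / ((s - 1) / 2.0) for s in shape
    ]
    U = np.meshgrid(*axes, indexing="ij")
    mask = sum(u ** 2 for u in U) / 0.9 ** 2 <= 1.0
    field = np.zeros(shape)
    n_modes = 8
    freqs = rng.integers(1, 4, size=(n_modes, 3))
    phases = rng.uniform(0, 2 * np.pi, size=(n_modes, 3))
    amps = rng.standard_normal(n_modes)
    for k in range(n_modes):
        mode = np.ones(shape)
        for a in range(3):
            mode = mode * np.cos(np.pi * freqs[k, a] * U[a] + phases[k, a])
        field += amps[k] * mode
    field = 100.0 + 20.0 * field / max(field.std(), 1e-12)
    template = np.where(mask, np.maximum(field, 1.0), 0.0)
    return template, mask


def generate_subject_volume(
    template: np.ndarray,
    mask: np.ndarray,
    group_effect,
    noise_sds: tuple[float, float],
    seed=None,
) -> np.ndarray:
    """Template + smooth subject field + voxel noise, with regional atrophy.

    ``group_effect`` is an iterable of :class:`RegionEffect`; outside the
    affected regions the volume is exactly template + smooth subject field +
    i.i.d. voxel noise.
    """
    subject_sd, voxel_sd = noise_sds
    if subject_sd <= 0 or voxel_sd <= 0:
        raise ParameterError("noise SDs must be positive")
    rng = np.random.default_rng(seed)
    smooth = gaussian_filter(
        rng.standard_normal(template.shape), sigma=_SUBJECT_FIELD_SIGMA
    )
    smooth *= subject_sd / max(smooth.std(), 1e-12)
    volume = template + smooth + rng.normal(0.0, voxel_sd, size=template.shape)
    interior_mean = float(template[mask].mean()) if mask.any() else 0.0
    for effect in group_effect:
        sl = effect.patch.slices
        region = volume[sl]
        region = interior_mean + (1.0 - effect.attenuation) * (region - interior_mean)
        if effect.decorrelation > 0.0:
            replacement = (
                region.mean()
                + rng.standard_normal(region.shape) * region.std()
            )
            region = (1.0 - effect.decorrelation) * region \
                + effect.decorrelation * replacement
        volume[sl] = region
    return volume


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Volumes-branch cohort generator.

    Group-dependent atrophy is applied to the affected nodes' patch regions
    for every designated case group (by default all groups after the first,
    which acts as the control arm).
    """
    config.validate()
    ss = as_seed_sequence(config.seed)
    template_seed, *subject_seeds = ss.spawn(
        1 + sum(config.group_sizes.values())
    )
    template, mask = generate_template(config.volume_shape, template_seed)
    grid = build_patch_grid(
        mask, config.patch_dims, config.retention_threshold
    )
    affected = frozenset(int(i) for i in config.affected_nodes)
    if any(i < 0 or i >= grid.n_nodes for i in affected):
        raise ParameterError(
            f"affected_nodes must be valid node indices 0..{grid.n_nodes - 1}"
        )
    groups = list(config.group_sizes)
    case_groups = (
        set(config.case_groups) if config.case_groups is not None
        else set(groups[1:])
    )
    unknown = case_groups - set(groups)
    if unknown:
        raise ParameterError(f"case_groups not in group_sizes: {sorted(unknown)}")

    eff_a = config.effect_size * config.attenuation
    eff_d = config.effect_size * config.decorrelation
    case_effects = [
        RegionEffect(grid.patches[i], attenuation=eff_a, decorrelation=eff_d)
        for i in sorted(affected)
    ]
    has_effect = config.effect_size > 0 and bool(affected) and bool(case_groups)

    subject_ids, labels, volumes = [], [], []
    k = 0
    for group in groups:
        for j in range(config.group_sizes[group]):
            effects = case_effects if (group in case_groups and has_effect) else []
            volumes.append(
                generate_subject_volume(
                    template, mask, effects,
                    (config.subject_noise_sd, config.voxel_noise_sd),
                    seed=subject_seeds[k],
                )
            )
            subject_ids.append(f"{group}-{j:03d}")
            labels.append(group)
            k += 1
    return SyntheticCohort(
        subject_ids=subject_ids,
        labels=labels,
        truth=affected if has_effect else frozenset(),
        provenance={"branch": "volumes", "config": config.__dict__.copy()},
        volumes=volumes,
        mask=mask,
        grid=grid,
    )


def _latent_template(rng, n_nodes: int, rank: int, scale: float) -> np.ndarray:
    """Correlation-like symmetric template with unit diagonal.

    Low-rank Gram structure rescaled so off-diagonal entries spread over
    roughly [-scale, scale].
    """
    V = rng.standard_normal((n_nodes, rank))
    G = V @ V.T
    d = np.sqrt(np.diag(G))
    B = G / np.outer(d, d) * scale
    np.fill_diagonal(B, 1.0)
    return B


def generate_connectivity_cohort(
    n_nodes: int,
    group_sizes: dict,
    affected_nodes=(),
    effect_size: float = 0.0,
    seed=None,
    entry_noise_sd: float = 0.12,
    base_scale: float = 0.6,
    row_mix: float = 0.06,
    block_target: float = 0.2,
    latent_rank: int = 3,
) -> SyntheticCohort:
    """Matrices-branch cohort generator (no image processing involved).

    Subjects share a latent connectivity template ``B`` (low-rank Gram
    structure, unit diagonal); each subject's matrix is ``B`` plus symmetric
    i.i.d. entry noise, clipped to [-1, 1]. With ``effect_size`` = 0 all
    subjects are i.i.d., so group labels are exchangeable.

    For case-group subjects (every group after the first), the rows/columns
    of the affected nodes are perturbed with magnitude ``effect_size`` in
    two tiers:

    * entries *between* two affected nodes are moved strongly toward a
      sign-flipped target of fixed magnitude ``block_target`` — this
      carries most of the detectable group difference, and is visible only
      in affected nodes' own connectivity patterns (other nodes' patterns
      do not contain within-block entries), keeping the ground truth
      unambiguous;
    * entries between an affected and an unaffected node are rotated
      weakly (weight ``row_mix * effect_size``) toward an independent
      alternative template — this reshapes the affected node's whole
      pattern (so a *single* affected node is still the top-scoring node
      at large effect) while the per-coordinate spill into other nodes'
      patterns stays well below the entry noise.
    """
    if n_nodes < 3:
        raise SizingError(f"n_nodes must be >= 3, got {n_nodes}")
    sizes = list(group_sizes.values())
    if len(sizes) < 2:
        raise DesignError("need at least 2 groups")
    if any(s < 2 for s in sizes):
        raise DesignError(
            f"every group needs >= 2 subjects (pseudo-F undefined); got {group_sizes}"
        )
    if not 0.0 <= effect_size <= 1.0:
        raise ParameterError(f"effect_size must be in [0, 1], got {effect_size}")
    affected = sorted(int(i) for i in affected_nodes)
    if any(i < 0 or i >= n_nodes for i in affected):
        raise ParameterError(f"affected_nodes must be in 0..{n_nodes - 1}")

    n = sum(sizes)
    ss = as_seed_sequence(seed)
    base_seed, *subject_seeds = ss.spawn(1 + n)
    rng0 = np.random.default_rng(base_seed)
    B = _latent_template(rng0, n_nodes, latent_rank, base_scale)
    Q = _latent_template(rng0, n_nodes, latent_rank, base_scale)

    has_effect = effect_size > 0 and bool(affected)
    B_case = B.copy()
    if has_effect:
        w = row_mix * effect_size
        for i in affected:
            row = (1.0 - w) * B[i, :] + w * Q[i, :]
            B_case[i, :] = row
            B_case[:, i] = row
        for pos, i in enumerate(affected):
            for j in affected[pos + 1:]:
                target = (
                    -np.sign(B[i, j]) * block_target
                    if B[i, j] != 0.0 else block_target
                )
                value = (1.0 - effect_size) * B[i, j] + effect_size * target
                B_case[i, j] = B_case[j, i] = value
        np.fill_diagonal(B_case, 1.0)

    groups = list(group_sizes)
    case = set(groups[1:])
    subject_ids, labels = [], []
    matrices = np.empty((n, n_nodes, n_nodes))
    k = 0
    for group in groups:
        template = B_case if (group in case and has_effect) else B
        for j in range(group_sizes[group]):
            rng = np.random.default_rng(subject_seeds[k])
            noise = rng.standard_normal((n_nodes, n_nodes)) * entry_noise_sd
            noise = (noise + noise.T) / np.sqrt(2.0)
            M = template + noise
            np.clip(M, -1.0, 1.0, out=M)
            np.fill_diagonal(M, 1.0)
            matrices[k] = M
            subject_ids.append(f"{group}-{j:03d}")
            labels.append(group)
            k += 1
    return SyntheticCohort(
        subject_ids=subject_ids,
        labels=labels,
        truth=frozenset(affected) if has_effect else frozenset(),
        provenance={
            "branch": "matrices",
            "n_nodes": n_nodes,
            "group_sizes": dict(group_sizes),
            "affected_nodes": affected,
            "effect_size": effect_size,
            "seed": seed,
            "entry_noise_sd": entry_noise_sd,
            "base_scale": base_scale,
            "row_mix": row_mix,
            "block_target": block_target,
            "latent_rank": latent_rank,
        },
        matrices=matrices,
    )
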