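"""Synthetic three-group resting-state cohort with planted ground truth.

Real subject-level fMRI for the cohorts this pipeline targets (normal
controls and the two stages of subcortical ischemic vascular disease,
cognitive-impairment-no-dementia and dementia) is rarely shareable, so
the package generates a surrogate cohort in which the answer is known:

* a block-structured population correlation matrix over 90 regions,
  with stronger correlation inside each of six lobe groups than
  between them;
* multiplicative, group-graded attenuation of all off-diagonal
  couplings (controls untouched, patient groups progressively
  weakened), plus an extra planted attenuation on a small connected
  edge set, emulating a focal disconnection;
* band-limited Gaussian region signals drawn from each subject's
  covariance;
* nuisance covariates (age, gender, education) and cognitive scores
  (MMSE, MoCA and the clinical scales HIS/GDS/CDR/ADL) tied
  monotonically to each subject's degradation factor.

Every quantity downstream — metric group ordering, the edges the
network-based statistic should recover, score/metric correlations — is
therefore checkable against the generating truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import regions

GROUPS = ("NC", "SIVCIND", "SIVaD")
PATIENT_GROUPS = ("SIVCIND", "SIVaD")

#: Cognitive/clinical score summaries used as generation anchors:
#: group -> score -> (mean, sd, low, high).
SCORE_ANCHORS: dict[str, dict[str, tuple[float, float, float, float]]] = {
    "NC": {
        "MMSE": (28.5, 0.8, 27, 30),
        "MoCA": (28.0, 0.9, 27, 30),
    },
    "SIVCIND": {
        "MMSE": (24.1, 1.9, 22, 28),
        "MoCA": (17.9, 4.9, 8, 24),
        "HIS": (8.5, 1.8, 7, 12),
        "GDS": (3.3, 0.7, 2, 5),
        "CDR": (0.5, 0.2, 0, 0.5),
        "ADL": (15.0, 3.2, 12, 25),
    },
    "SIVaD": {
        "MMSE": (14.2, 5.4, 4, 22),
        "MoCA": (8.9, 4.5, 1, 20),
        "HIS": (8.9, 4.5, 8, 17),
        "GDS": (4.7, 1.0, 4, 7),
        "CDR": (1.5, 0.7, 1, 3),
        "ADL": (14.4, 2.5, 12, 19),
    },
}

# Affine MMSE/MoCA maps anchored at the control (factor 1.0) mean and
# a severe-degradation reference point (factor 0.70).
_MMSE_ANCHOR = (0.70, 14.2, 1.0, 28.5)
_MOCA_ANCHOR = (0.70, 8.9, 1.0, 28.0)

_SPD_FLOOR = 1e-6


def _default_planted_edges() -> tuple[tuple[int, int], ...]:
    """A connected 10-edge path through frontal/temporal/parietal regions.

    0-based region indices into the default 90-region table; the path
    runs middle-frontal -> superior-temporal -> inferior-parietal
    territory in the left hemisphere plus its right homologues.
    """
    # indices (0-based) of: Frontal_Mid_L(6), Frontal_Mid_R(7),
    # Frontal_Sup_L(2), Temporal_Sup_L(80), Temporal_Sup_R(81),
    # Temporal_Mid_L(84), Parietal_Inf_L(60), Parietal_Inf_R(61),
    # SupraMarginal_L(62), Angular_L(64), Precuneus_L(66)
    chain = [6, 2, 80, 84, 60, 62, 64, 66, 7, 81, 61]
    return tuple((min(a, b), max(a, b)) for a, b in zip(chain[:-1], chain[1:]))


@dataclass(frozen=True)
class CohortSpec:
    """Generation parameters for one synthetic cohort.

    Defaults reproduce the study conditions downstream stages are
    validated under: 19/20/20 subjects, 90 regions in six lobe blocks,
    230 timepoints, and attenuation factors 1.00/0.90/0.75.
    """

    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"NC": 19, "SIVCIND": 20, "SIVaD": 20}
    )
    n_regions: int = 90
    n_timepoints: int = 230
    lobe_sizes: Sequence[int] | None = None
    within_lobe_corr: float = 0.68
    within_peri_corr: float = 0.40
    within_core_frac: float = 0.5
    between_lobe_corr: float = 0.18
    homotopic_corr: float | None = 0.78
    assoc_modules: int = 0
    assoc_module_size: int = 10
    association_corr: float = 0.50
    n_hubs: int = 6
    hub_corr: float = 0.88
    hub_spoke_corr: float = 0.55
    hub_vulnerability: float = 1.0
    nonhub_vulnerability: float = 0.25
    group_attenuation: Mapping[str, float] = field(
        default_factory=lambda: {"NC": 1.00, "SIVCIND": 0.90, "SIVaD": 0.75}
    )
    planted_edges: Sequence[tuple[int, int]] = field(
        default_factory=_default_planted_edges
    )
    planted_factor: float = 0.75
    covariate_effect: Mapping[str, float] = field(
        default_factory=lambda: {"age": 0.0, "gender": 0.0, "education": 0.0}
    )
    longrange_gamma: float = 1.8
    periph_gamma: float = 0.5
    shortrange_gamma: float = 0.0
    node_gamma: float = 2.0
    lobe_weight: Mapping[str, float] = field(
        default_factory=lambda: {
            "frontal": 1.0,
            "temporal": 1.0,
            "parietal": 1.0,
            "medial temporal": 0.6,
            "occipital": 0.6,
            "subcortical": 0.6,
        }
    )
    measurement_noise: float = 0.0
    noise_shape: float = 0.5
    subject_jitter_sd: float = 0.015
    factor_jitter_sd: float = 0.01
    score_noise_sd: float = 1.5
    band_hz: tuple[float, float] | None = (0.01, 0.08)
    sampling_interval: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.within_lobe_corr < 1.0):
            raise ValueError("within_lobe_corr must lie in (0, 1)")
        if not (0.0 < self.within_peri_corr <= self.within_lobe_corr):
            raise ValueError("within_peri_corr must lie in (0, within_lobe_corr]")
        if not (0.0 <= self.within_core_frac <= 1.0):
            raise ValueError("within_core_frac must lie in [0, 1]")
        if not (0.0 <= self.between_lobe_corr < self.within_peri_corr):
            raise ValueError("between_lobe_corr must lie in [0, within_peri_corr)")
        att = dict(self.group_attenuation)
        for g, a in att.items():
            if not (0.0 < a <= 1.0):
                raise ValueError(f"attenuation for {g} must lie in (0, 1]")
        ordered = [att[g] for g in GROUPS if g in att]
        if any(a < b for a, b in zip(ordered[:-1], ordered[1:])):
            raise ValueError("attenuation must be ordered NC >= SIVCIND >= SIVaD")
        if self.lobe_sizes is not None:
            sizes = list(self.lobe_sizes)
            if len(sizes) != 6 or any(s <= 0 for s in sizes):
                raise ValueError("lobe_sizes must be 6 positive integers")
            if sum(sizes) != self.n_regions:
                raise ValueError("lobe_sizes must sum to n_regions")
        for i, j in self.planted_edges:
            if not (0 <= i < self.n_regions and 0 <= j < self.n_regions and i != j):
                raise ValueError(f"planted edge ({i}, {j}) out of range")

    def lobe_labels(self) -> list[str]:
        """Lobe label per region: explicit contiguous blocks if
        ``lobe_sizes`` is set, otherwise the packaged 90-region table."""
        if self.lobe_sizes is not None:
            labels: list[str] = []
            for lobe, size in zip(regions.LOBES, self.lobe_sizes):
                labels.extend([lobe] * size)
            return labels
        if self.n_regions == 90:
            return regions.lobe_labels(regions.default_region_table())
        # fallback: near-equal contiguous blocks
        base, extra = divmod(self.n_regions, 6)
        labels = []
        for k, lobe in enumerate(regions.LOBES):
            labels.extend([lobe] * (base + (1 if k < extra else 0)))
        return labels

    def region_names(self) -> list[str]:
        if self.lobe_sizes is None and self.n_regions == 90:
            return regions.region_names(regions.default_region_table())
        return [f"R{i + 1:03d}" for i in range(self.n_regions)]

    def hemisphere_labels(self) -> list[str] | None:
        """L/R per region (atlas interleaving) when using the packaged
        table; None for generic contiguous-block cohorts."""
        if self.lobe_sizes is None and self.n_regions == 90:
            table = regions.default_region_table()
            return list(table["hemisphere"])
        return None

    def longrange_mask(self) -> np.ndarray:
        """Boolean mask of 'long-range' (between-lobe) edges.

        These are the couplings carried by long association fibers,
        which small-vessel ischemic damage degrades disproportionately;
        short intra-lobe circuits (including the homotopic pairs) are
        comparatively spared."""
        lobes = np.asarray(self.lobe_labels())
        mask = lobes[:, None] != lobes[None, :]
        np.fill_diagonal(mask, False)
        return mask

    def association_modules(self) -> list[list[int]]:
        """Distributed association modules planted in the base.

        ``assoc_modules`` groups of ``assoc_module_size`` regions each,
        drawn (seeded, deterministically) from the fully weighted lobes
        (``lobe_weight == 1``: frontal/temporal/parietal by default).
        Members of a module are mutually coupled at
        ``association_corr``, emulating the distributed resting-state
        subnetworks (default-mode, fronto-parietal, ...) whose
        long-range limbs are what small-vessel ischemic damage severs.
        """
        if self.assoc_modules == 0 or self.assoc_module_size < 2:
            return []
        lobes = np.asarray(self.lobe_labels())
        w = dict(self.lobe_weight)
        eligible = np.flatnonzero(
            np.array([w.get(l, 1.0) for l in lobes]) >= 1.0
        )
        if self.assoc_module_size > eligible.size:
            raise ValueError(
                f"assoc_module_size={self.assoc_module_size} exceeds the "
                f"{eligible.size} eligible regions"
            )
        rng = np.random.default_rng(np.random.SeedSequence([0x5EED]))
        return [
            sorted(
                int(r)
                for r in rng.choice(eligible, size=self.assoc_module_size, replace=False)
            )
            for _ in range(self.assoc_modules)
        ]

    def association_edges(self) -> list[tuple[int, int]]:
        """All distinct region pairs joined by some association module."""
        pairs: set[tuple[int, int]] = set()
        for members in self.association_modules():
            for ai, a in enumerate(members):
                for b in members[ai + 1 :]:
                    pairs.add((a, b))
        return sorted(pairs)

    def within_core_mask(self) -> np.ndarray:
        """Boolean mask of same-lobe 'core' edges.

        A seeded random ``within_core_frac`` of each lobe's internal
        pairs is designated core (short U-fiber circuitry, strong and
        comparatively spared); the rest is vulnerable periphery.
        Homotopic pairs are always core.
        """
        lobes = np.asarray(self.lobe_labels())
        same = lobes[:, None] == lobes[None, :]
        np.fill_diagonal(same, False)
        iu = np.triu_indices(self.n_regions, k=1)
        same_u = same[iu]
        rng = np.random.default_rng(np.random.SeedSequence([0xC07E]))
        core_u = same_u & (rng.random(same_u.size) < self.within_core_frac)
        mask = np.zeros((self.n_regions, self.n_regions), dtype=bool)
        mask[iu] = core_u
        mask = mask | mask.T
        if self.hemisphere_labels() is not None:
            for k in range(self.n_regions // 2):
                if same[2 * k, 2 * k + 1]:
                    mask[2 * k, 2 * k + 1] = mask[2 * k + 1, 2 * k] = True
        return mask

    def hub_regions(self) -> list[int]:
        """Rich-club hub regions (seeded, deterministic).

        ``n_hubs`` regions drawn from the fully weighted lobes
        (``lobe_weight == 1``: frontal/temporal/parietal by default).
        Hubs are mutually coupled at ``hub_corr`` and coupled to every
        other region at least at ``hub_spoke_corr``, forming the strong
        long-range skeleton that makes the healthy connectome both
        integrated and fault-tolerant."""
        if self.n_hubs == 0:
            return []
        lobes = np.asarray(self.lobe_labels())
        w = dict(self.lobe_weight)
        eligible = np.flatnonzero(
            np.array([w.get(l, 1.0) for l in lobes]) >= 1.0
        )
        if self.n_hubs > eligible.size:
            raise ValueError(
                f"n_hubs={self.n_hubs} exceeds the {eligible.size} eligible regions"
            )
        rng = np.random.default_rng(np.random.SeedSequence([0x44B5]))
        return sorted(
            int(r) for r in rng.choice(eligible, size=self.n_hubs, replace=False)
        )

    def node_vulnerability(self) -> np.ndarray:
        """Per-region vulnerability to focal ischemic damage, in [0, 1].

        Hub regions carry vulnerabilities spread evenly across
        ``(0.3 .. 1.9) * hub_vulnerability``
        — the rich club is the best-documented casualty of small-vessel
        disease, but its members are not struck all at once: the spread
        makes hub failure progressive, with the most vulnerable hubs
        lost at the mild stage and the rest only at the dementia stage.
        Other
        regions get a seeded, right-skewed draw (squared uniform, so a
        few regions are clearly affected and most barely) scaled by
        ``nonhub_vulnerability`` and the region's ``lobe_weight``.
        The same territories are hit in every subject, harder the
        lower the subject's degradation factor.
        """
        rng = np.random.default_rng(np.random.SeedSequence([0xB10B]))
        u = rng.random(self.n_regions) ** 2
        w = np.array(
            [float(dict(self.lobe_weight).get(l, 1.0)) for l in self.lobe_labels()]
        )
        v = u * w * self.nonhub_vulnerability
        hubs = self.hub_regions()
        if hubs:
            if len(hubs) == 1:
                spread = np.array([1.0])
            else:
                spread = np.linspace(0.3, 1.9, len(hubs))
            perm = rng.permutation(len(hubs))
            v[np.asarray(hubs)] = self.hub_vulnerability * spread[perm]
        return v

    def attenuation_exponent(self) -> np.ndarray:
        """Per-edge degradation exponent E: a subject with factor g has
        edge (i, j) scaled by ``g ** E[i, j]``.

        Two mechanisms mirror the damage in small-vessel ischemic
        disease.  Edge tiers: between-lobe edges (long association
        fibers, see :meth:`longrange_mask`) use ``longrange_gamma``;
        same-lobe periphery edges use ``periph_gamma``; same-lobe core
        edges (short U-fibers, comparatively spared) use
        ``shortrange_gamma``; each modulated by the mean
        ``lobe_weight`` of the endpoints.  Focal node damage: every
        edge additionally carries ``node_gamma`` times the summed
        :meth:`node_vulnerability` of its endpoints, so the couplings
        of a few ischemic territories collapse outright in degraded
        subjects.
        """
        lr = self.longrange_mask()
        core = self.within_core_mask()
        e = np.where(lr, self.longrange_gamma, self.periph_gamma)
        e[core] = self.shortrange_gamma
        w = np.array(
            [float(dict(self.lobe_weight).get(l, 1.0)) for l in self.lobe_labels()]
        )
        e = e * (w[:, None] + w[None, :]) / 2.0
        v = self.node_vulnerability()
        e = e + self.node_gamma * (v[:, None] + v[None, :])
        np.fill_diagonal(e, 0.0)
        return e


@dataclass
class GroundTruth:
    """What the generator planted, for validation of downstream stages."""

    group_covariance: dict[str, np.ndarray]
    planted_edges: list[tuple[int, int]]
    degradation_factor: dict[str, float]  # subject_id -> factor


def _repair_spd(mat: np.ndarray, floor: float = _SPD_FLOOR) -> np.ndarray:
    """Nearest-SPD surrogate: clip eigenvalues at a positive floor,
    reconstruct, renormalize the diagonal to 1."""
    sym = (mat + mat.T) / 2.0
    vals, vecs = np.linalg.eigh(sym)
    if vals.min() >= floor:
        out = sym
    else:
        out = (vecs * np.clip(vals, floor, None)) @ vecs.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    check = np.linalg.eigvalsh((out + out.T) / 2.0).min()
    if check <= 0:
        raise RuntimeError(
            f"covariance not positive definite after repair (min eigenvalue {check:.3e})"
        )
    return (out + out.T) / 2.0


def make_base_covariance(spec: CohortSpec) -> np.ndarray:
    """Block-structured population correlation matrix.

    Entries equal ``within_lobe_corr`` for same-lobe pairs and
    ``between_lobe_corr`` otherwise; left/right homologue pairs (a
    hallmark of resting-state correlation structure) are raised to
    ``homotopic_corr`` when the packaged parcellation provides
    hemisphere labels.  Unit diagonal; projected to the nearest SPD
    matrix if the raw pattern is not positive definite.
    """
    labels = np.asarray(spec.lobe_labels())
    same = labels[:, None] == labels[None, :]
    core = spec.within_core_mask()
    cov = np.where(same, spec.within_peri_corr, spec.between_lobe_corr)
    cov[core] = spec.within_lobe_corr
    for i, j in spec.association_edges():
        cov[i, j] = cov[j, i] = max(cov[i, j], spec.association_corr)
    hubs = spec.hub_regions()
    if hubs:
        h = np.asarray(hubs)
        cov[h, :] = np.maximum(cov[h, :], spec.hub_spoke_corr)
        cov[:, h] = np.maximum(cov[:, h], spec.hub_spoke_corr)
        hh = np.ix_(h, h)
        cov[hh] = np.maximum(cov[hh], spec.hub_corr)
    if spec.homotopic_corr is not None and spec.hemisphere_labels() is not None:
        for k in range(spec.n_regions // 2):
            cov[2 * k, 2 * k + 1] = cov[2 * k + 1, 2 * k] = spec.homotopic_corr
    np.fill_diagonal(cov, 1.0)
    return _repair_spd(cov)


def subject_covariance(
    base: np.ndarray,
    group_factor: float,
    planted_edges: Sequence[tuple[int, int]] = (),
    planted_factor: float = 1.0,
    subject_jitter_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    attenuation_exponent: np.ndarray | None = None,
) -> np.ndarray:
    """One subject's population covariance.

    Off-diagonals of ``base`` are scaled by ``group_factor`` (or, when
    an ``attenuation_exponent`` matrix E is given, edgewise by
    ``group_factor ** E[i, j]``); the planted edges additionally by
    ``planted_factor``; symmetric zero-mean Gaussian jitter is added to
    the off-diagonals, then the matrix is SPD-repaired with its
    diagonal held at 1.

    The exponent matrix lets the damage fall disproportionately on
    long-range couplings — small-vessel ischemic disease disconnects
    long association and commissural fibers while largely sparing
    short intra-lobe circuits — which is what makes degraded networks
    genuinely less efficient once edge weights are cost-normalized
    downstream.
    """
    if not (0.0 < group_factor <= 1.0):
        raise ValueError("group_factor must lie in (0, 1]")
    if not (0.0 < planted_factor <= 1.0):
        raise ValueError("planted_factor must lie in (0, 1]")
    n = base.shape[0]
    if attenuation_exponent is None:
        factor = np.full((n, n), group_factor)
    else:
        e = np.asarray(attenuation_exponent, dtype=float)
        if e.shape != base.shape:
            raise ValueError("attenuation_exponent shape must match base")
        factor = group_factor**e
    cov = base * factor
    np.fill_diagonal(cov, 1.0)
    for i, j in planted_edges:
        cov[i, j] *= planted_factor
        cov[j, i] = cov[i, j]
    if subject_jitter_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        noise = rng.normal(0.0, subject_jitter_sd, size=(n, n))
        noise = (noise + noise.T) / 2.0
        np.fill_diagonal(noise, 0.0)
        cov = cov + noise
    if subject_jitter_sd > 0 or planted_edges or group_factor < 1.0:
        cov = _repair_spd(cov)
    return cov


def simulate_timeseries(
    cov: np.ndarray, n_timepoints: int, rng: np.random.Generator
) -> np.ndarray:
    """T x N zero-mean Gaussian draws with the given covariance."""
    if n_timepoints < 2:
        raise ValueError("need at least 2 timepoints")
    chol = np.linalg.cholesky(cov)
    white = rng.standard_normal((n_timepoints, cov.shape[0]))
    return white @ chol.T


def _affine_score(anchor: tuple[float, float, float, float], factor: float) -> float:
    f0, v0, f1, v1 = anchor
    return v0 + (v1 - v0) * (factor - f0) / (f1 - f0)


def generate_scores(
    degradation_factor: float,
    group: str,
    spec: CohortSpec,
    rng: np.random.Generator | None = None,
) -> dict[str, float]:
    """Cognitive and clinical scores for one subject.

    MMSE and MoCA increase affinely with the degradation factor (1.0 =
    intact connectivity) plus Gaussian noise, clipped to the 0-30 scale;
    clinical scales (HIS, GDS, CDR, ADL) are drawn inside their
    group-typical ranges for patient groups and absent for controls.
    """
    if not (0.0 < degradation_factor <= 1.0):
        raise ValueError("degradation_factor must lie in (0, 1]")
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    if rng is None:
        rng = np.random.default_rng()
    noise = spec.score_noise_sd
    scores = {
        "MMSE": float(
            np.clip(
                _affine_score(_MMSE_ANCHOR, degradation_factor)
                + rng.normal(0.0, noise),
                0.0,
                30.0,
            )
        ),
        "MoCA": float(
            np.clip(
                _affine_score(_MOCA_ANCHOR, degradation_factor)
                + rng.normal(0.0, noise),
                0.0,
                30.0,
            )
        ),
    }
    if group in PATIENT_GROUPS:
        for name in ("HIS", "GDS", "CDR", "ADL"):
            mean, sd, lo, hi = SCORE_ANCHORS[group][name]
            scores[name] = float(np.clip(rng.normal(mean, sd), lo, hi))
    else:
        for name in ("HIS", "GDS", "CDR", "ADL"):
            scores[name] = float("nan")
    return scores


def generate_cohort(
    spec: CohortSpec,
) -> tuple[list[np.ndarray], pd.DataFrame, GroundTruth]:
    """Generate the full cohort.

    Returns per-subject time series (each ``n_timepoints x n_regions``),
    a metadata table (subject_id, group, age, gender, education, scores,
    degradation_factor) and the planted ground truth.  Fully
    reproducible from ``spec.seed``.
    """
    if any(n <= 0 for n in spec.n_per_group.values()):
        raise ValueError("every group needs at least one subject")
    rng = np.random.default_rng(spec.seed)
    base = make_base_covariance(spec)
    att = dict(spec.group_attenuation)
    expo = spec.attenuation_exponent()
    group_cov = {
        g: subject_covariance(
            base,
            att[g],
            spec.planted_edges,
            spec.planted_factor,
            attenuation_exponent=expo,
        )
        for g in spec.n_per_group
    }
    effects = dict(spec.covariate_effect)
    cov_refs = {"age": 67.0, "gender": 0.5, "education": 8.0}

    series: list[np.ndarray] = []
    rows = []
    factors: dict[str, float] = {}
    sid = 0
    for group in GROUPS:
        if group not in spec.n_per_group:
            continue
        for _ in range(spec.n_per_group[group]):
            sid += 1
            subject_id = f"sub-{sid:03d}"
            factor = float(
                np.clip(
                    att[group] + rng.normal(0.0, spec.factor_jitter_sd),
                    0.05,
                    1.0,
                )
            )
            age = float(np.clip(rng.normal(67.0, 7.0), 47.0, 85.0))
            gender = int(rng.integers(0, 2))
            education = float(np.clip(rng.normal(8.0, 3.5), 0.0, 15.0))
            cov = subject_covariance(
                base,
                factor,
                spec.planted_edges,
                spec.planted_factor,
                spec.subject_jitter_sd,
                rng,
                attenuation_exponent=expo,
            )
            shift = sum(
                effects.get(name, 0.0) * (value - cov_refs[name])
                for name, value in (
                    ("age", age),
                    ("gender", gender),
                    ("education", education),
                )
            )
            if shift != 0.0:
                od = ~np.eye(cov.shape[0], dtype=bool)
                cov = cov.copy()
                cov[od] = np.clip(cov[od] + shift, -0.95, 0.95)
                cov = _repair_spd(cov)
            ts = simulate_timeseries(cov, spec.n_timepoints, rng)
            sigma = spec.measurement_noise * max(1.0 - factor, 0.0) ** spec.noise_shape
            if sigma > 0:
                # degraded subjects are also noisier scans (lower SNR,
                # more motion residue), which uniformly shrinks their
                # measured correlations
                ts = ts + rng.normal(0.0, sigma, size=ts.shape)
            if spec.band_hz is not None:
                # band-limit the signals to the slow-fluctuation range;
                # preserves the planted correlation structure
                from .connectome import ROITimeSeries, bandpass

                ts = bandpass(
                    ROITimeSeries(ts, spec.region_names(), spec.sampling_interval),
                    *spec.band_hz,
                ).values
            scores = generate_scores(factor, group, spec, rng)
            series.append(ts)
            factors[subject_id] = factor
            rows.append(
                {
                    "subject_id": subject_id,
                    "group": group,
                    "age": age,
                    "gender": gender,
                    "education": education,
                    **scores,
                    "degradation_factor": factor,
                }
            )
    meta = pd.DataFrame(rows)
    truth = GroundTruth(
        group_covariance=group_cov,
        planted_edges=[tuple(e) for e in spec.planted_edges],
        degradation_factor=factors,
    )
    return series, meta, truth


def spec_to_dict(spec: CohortSpec) -> dict:
    d = dataclasses.asdict(spec)
    d["n_per_group"] = dict(spec.n_per_group)
    d["group_attenuation"] = dict(spec.group_attenuation)
    d["covariate_effect"] = dict(spec.covariate_effect)
    d["lobe_weight"] = dict(spec.lobe_weight)
    d["planted_edges"] = [list(e) for e in spec.planted_edges]
    return d


def spec_from_dict(d: Mapping) -> CohortSpec:
    d = dict(d)
    if "planted_edges" in d:
        d["planted_edges"] = tuple(tuple(e) for e in d["planted_edges"])
    if "lobe_sizes" in d and d["lobe_sizes"] is not None:
        d["lobe_sizes"] = tuple(d["lobe_sizes"])
    if "band_hz" in d and d["band_hz"] is not None:
        d["band_hz"] = tuple(d["band_hz"])
    return CohortSpec(**d)
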