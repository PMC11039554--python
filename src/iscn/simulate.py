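"""Synthetic multi-site cohort generator with known ground truth.

Voxel GMV values are Gaussian per region, which makes every downstream
quantity analytically tractable: the symmetric KLD between two Gaussian
regions has the closed form (mu1-mu2)^2/sigma^2 (equal variances), so
iSCN edges have known targets.  Site effects enter as an additive shift
on voxel means and a multiplicative factor on voxel SDs; group effects
shift designated regions' means or pull edge partners' means together;
age and gender act linearly on the mean; the HAMD-17 symptom score of
patients is a linear function of one designated edge's realized KLS plus
noise, clipped to the clinical inclusion range [18, 52].
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from iscn.cohort import NetworkAssignment, Phenotype, RegionalVoxelSamples, YEO_LABELS
from iscn.network import pair_kls


@dataclasses.dataclass
class SimulationSpec:
    """Ground-truth parameters of a synthetic multi-site cohort.

    Region labels are 1-based (1..n_regions).  ``effect_regions`` entries
    are ``(region, delta)``: the patient voxel mean of that region is
    shifted by delta.  ``effect_edges`` entries are ``(a, b, delta)``:
    the patient mean of region a is moved toward (delta > 0) or away
    from (delta < 0) region b's mean by the fraction delta of their
    separation, so delta = 1 makes the two distributions identical in
    mean and maximally strengthens the (a, b) edge.  ``hamd_edge`` is
    ``((a, b), coef, noise_sd)``: patient HAMD-17 is built from the
    z-scored realized KLS of edge (a, b), giving a designed partial
    correlation coef / sqrt(coef^2 + noise_sd^2).
    """

    n_patients: int = 60
    n_controls: int = 60
    n_sites: int = 3
    n_regions: int = 60
    voxels_per_region: int | tuple[int, int] = 200
    base_mean: Sequence[float] | None = None   # default: spread over [0.35, 0.85]
    base_sd: Sequence[float] | float = 0.08
    site_shift: Sequence[float] | None = None  # default: +/-0.02 alternating
    site_scale: Sequence[float] | None = None  # default: 10% SD inflation alternating
    effect_regions: Sequence[tuple[int, float]] = ()
    effect_edges: Sequence[tuple[int, int, float]] = ()
    age_slope: float = -0.002    # GMV decline per year of age
    gender_offset: float = 0.01  # additive mean offset for males
    hamd_edge: tuple[tuple[int, int], float, float] | None = None
    seed: int = 0

    def resolved_means(self) -> np.ndarray:
        if self.base_mean is not None:
            m = np.asarray(self.base_mean, dtype=float)
            if m.size != self.n_regions:
                raise ValueError("base_mean length must equal n_regions")
            return m
        # distinct means, deterministically shuffled so region index and
        # mean rank are not confounded
        m = np.linspace(0.35, 0.85, self.n_regions)
        np.random.default_rng(self.seed + 1).shuffle(m)
        return m

    def resolved_sds(self) -> np.ndarray:
        sd = np.broadcast_to(np.asarray(self.base_sd, dtype=float), (self.n_regions,)).copy()
        if (sd <= 0).any():
            raise ValueError("base_sd must be positive")
        return sd

    def resolved_site_effects(self) -> tuple[np.ndarray, np.ndarray]:
        if self.site_shift is None:
            shift = np.array([0.02 * ((-1) ** s) * (s > 0) for s in range(self.n_sites)])
        else:
            shift = np.asarray(self.site_shift, dtype=float)
        if self.site_scale is None:
            scale = np.array([1.0 + 0.1 * ((-1) ** s) * (s > 0) for s in range(self.n_sites)])
        else:
            scale = np.asarray(self.site_scale, dtype=float)
        if shift.size != self.n_sites or scale.size != self.n_sites:
            raise ValueError("site_shift/site_scale length must equal n_sites")
        if (scale <= 0).any():
            raise ValueError("site_scale must be positive")
        return shift, scale

    def validate(self) -> None:
        if self.n_patients < 0 or self.n_controls < 0 or self.n_patients + self.n_controls == 0:
            raise ValueError("cohort must contain at least one subject")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        for region, _ in self.effect_regions:
            if not (1 <= region <= self.n_regions):
                raise ValueError(f"effect region {region} outside 1..{self.n_regions}")
        edges = list(self.effect_edges)
        if self.hamd_edge is not None:
            (a, b), _, noise_sd = self.hamd_edge
            edges.append((a, b, 0.0))
            if noise_sd < 0:
                raise ValueError("hamd_edge noise SD must be >= 0")
        for a, b, _ in edges:
            for region in (a, b):
                if not (1 <= region <= self.n_regions):
                    raise ValueError(f"effect edge region {region} outside 1..{self.n_regions}")
            if a == b:
                raise ValueError(f"effect edge ({a},{b}) is a self-edge")


def null_spec(
    n_patients: int = 20,
    n_controls: int = 20,
    n_regions: int = 60,
    n_sites: int = 2,
    voxels_per_region: int = 200,
    seed: int = 0,
) -> SimulationSpec:
    """A cohort with no group, covariate or symptom effects (site effects kept)."""
    return SimulationSpec(
        n_patients=n_patients,
        n_controls=n_controls,
        n_sites=n_sites,
        n_regions=n_regions,
        voxels_per_region=voxels_per_region,
        age_slope=0.0,
        gender_offset=0.0,
        seed=seed,
    )


def default_assignment(n_regions: int) -> NetworkAssignment:
    """Round-robin Yeo-7 + subcortical labels over the region labels."""
    return NetworkAssignment({r: YEO_LABELS[(r - 1) % len(YEO_LABELS)] for r in range(1, n_regions + 1)})


HAMD_CENTER = 30.0
HAMD_SCALE = 6.0


def simulate_cohort(
    spec: SimulationSpec,
) -> tuple[list[RegionalVoxelSamples], list[Phenotype], dict]:
    """Draw a cohort of regional voxel samples plus phenotype and ground truth.

    Voxels of subject i, region r are N(mu, sd^2) with
    mu = base_mean_r + site_shift + age_slope*(age-40) + gender_offset*male
         + group terms,  sd = base_sd_r * site_scale.
    Returns (cohort, phenotype records, ground-truth dict); the truth dict
    records every injected effect for recovery tests.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    means = spec.resolved_means()
    sds = spec.resolved_sds()
    shift, scale = spec.resolved_site_effects()

    n = spec.n_patients + spec.n_controls
    groups = ["patient"] * spec.n_patients + ["control"] * spec.n_controls
    # balanced round-robin site assignment within each group
    sites = [i % spec.n_sites for i in range(spec.n_patients)] + [
        i % spec.n_sites for i in range(spec.n_controls)
    ]
    ages = rng.uniform(18, 65, n)
    genders = rng.choice(["male", "female"], n)
    episodes = [
        rng.choice(["first_episode_drug_naive", "recurrent", "other"], p=[0.4, 0.4, 0.2])
        if g == "patient"
        else "control"
        for g in groups
    ]

    # patient-specific region means
    patient_means = means.copy()
    for region, delta in spec.effect_regions:
        patient_means[region - 1] += delta
    for a, b, delta in spec.effect_edges:
        patient_means[a - 1] = patient_means[a - 1] + delta * (means[b - 1] - means[a - 1])

    if isinstance(spec.voxels_per_region, tuple):
        lo, hi = spec.voxels_per_region
        n_vox = rng.integers(lo, hi + 1, spec.n_regions)
    else:
        n_vox = np.full(spec.n_regions, int(spec.voxels_per_region))

    region_ids = list(range(1, spec.n_regions + 1))
    cohort: list[RegionalVoxelSamples] = []
    for i in range(n):
        mu = (patient_means if groups[i] == "patient" else means).copy()
        mu = mu + shift[sites[i]] + spec.age_slope * (ages[i] - 40.0)
        if genders[i] == "male":
            mu = mu + spec.gender_offset
        sd = sds * scale[sites[i]]
        samples = [rng.normal(mu[r], sd[r], n_vox[r]) for r in range(spec.n_regions)]
        cohort.append(RegionalVoxelSamples(f"sub-{i + 1:04d}", region_ids, samples))

    # HAMD-17 from the realized KLS of the designated edge (patients only)
    hamd: list[float | None] = [None] * n
    true_partial_r = None
    if spec.hamd_edge is not None and spec.n_patients > 0:
        (a, b), coef, noise_sd = spec.hamd_edge
        kls_vals = np.array(
            [pair_kls(cohort[i].samples[a - 1], cohort[i].samples[b - 1]) for i in range(spec.n_patients)]
        )
        z = (kls_vals - kls_vals.mean()) / kls_vals.std(ddof=0) if kls_vals.std() > 0 else np.zeros_like(kls_vals)
        latent = coef * z + rng.normal(0, noise_sd, spec.n_patients)
        denom = np.sqrt(coef**2 + noise_sd**2) if (coef, noise_sd) != (0, 0) else 1.0
        scores = np.clip(np.rint(HAMD_CENTER + HAMD_SCALE * latent / denom), 18, 52)
        for i in range(spec.n_patients):
            hamd[i] = float(scores[i])
        true_partial_r = coef / denom

    phenotype = [
        Phenotype(
            subject_id=cohort[i].subject_id,
            group=groups[i],
            site=f"site{sites[i] + 1}",
            age=float(ages[i]),
            gender=str(genders[i]),
            hamd17=hamd[i],
            episode=str(episodes[i]),
        )
        for i in range(n)
    ]

    truth = {
        "base_mean": means.tolist(),
        "base_sd": sds.tolist(),
        "site_shift": shift.tolist(),
        "site_scale": scale.tolist(),
        "effect_regions": [list(e) for e in spec.effect_regions],
        "effect_edges": [list(e) for e in spec.effect_edges],
        "age_slope": spec.age_slope,
        "gender_offset": spec.gender_offset,
        "hamd_edge": None
        if spec.hamd_edge is None
        else {
            "edge": list(spec.hamd_edge[0]),
            "coef": spec.hamd_edge[1],
            "noise_sd": spec.hamd_edge[2],
            "true_partial_r": true_partial_r,
        },
        "network_assignment": {str(r): default_assignment(spec.n_regions)[r] for r in region_ids},
        "seed": spec.seed,
    }
    return cohort, phenotype, truth


def simulate_edge_features(
    n_patients: int,
    n_controls: int,
    n_regions: int,
    effect_edges: Sequence[tuple[int, int, float]] = (),
    seed: int = 0,
    edge_sd: float = 1.0,
) -> tuple[np.ndarray, pd.DataFrame, np.ndarray]:
    """Gaussian edge-level features for inference-stage calibration.

    Bypasses the voxel/KDE layer: draws an independent N(0, edge_sd^2)
    value per edge and subject and adds ``delta`` to patients on each
    listed (a, b) edge (1-based region labels).  Used for null/recovery
    studies of the NBS machinery where the quantity under test is the
    inference, not the network construction.  Returns (subjects x edges
    feature matrix, phenotype frame, boolean mask of affected edges).
    """
    rng = np.random.default_rng(seed)
    n = n_patients + n_controls
    iu, ju = np.triu_indices(n_regions, 1)
    n_edges = iu.size
    y = rng.normal(0.0, edge_sd, (n, n_edges))
    mask = np.zeros(n_edges, dtype=bool)
    for a, b, delta in effect_edges:
        i, j = sorted((a - 1, b - 1))
        (k,) = np.flatnonzero((iu == i) & (ju == j))
        mask[k] = True
        y[:n_patients, k] += delta
    pheno = pd.DataFrame(
        {
            "subject_id": [f"sub-{i + 1:04d}" for i in range(n)],
            "group": ["patient"] * n_patients + ["control"] * n_controls,
            "site": ["site1"] * n,
            "age": rng.uniform(18, 65, n),
            "gender": rng.choice(["male", "female"], n),
        }
    )
    return y, pheno, mask
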