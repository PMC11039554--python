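"""Run configuration shared across pipeline stages."""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import yaml


@dataclasses.dataclass
class RunConfig:
    """Parameters governing a full iSCN pipeline run.

    Attributes
    ----------
    kde_points
        Number of evaluation points for each regional kernel density
        estimate (the value axis of the PDF grid).
    density_range
        ``"auto"`` to select the density-threshold range from the data
        (all networks connected at the lower bound, small-worldness of
        every network above ``small_world_floor`` at the upper bound), or
        an explicit ``(k_min, k_max, step)`` triple in percent.
    small_world_floor
        Minimum small-worldness sigma every subject's binary network must
        exceed for a density threshold to be retained.
    nbs_edge_p
        Two-tailed edge-level p threshold that defines suprathreshold
        edges entering the NBS component search.
    nbs_permutations
        Number of label permutations for the NBS max-component null.
    nbs_alpha
        Familywise alpha on the permutation max-component-size null.
    covariates
        Phenotype columns regressed out in group and clinical models.
    cv_folds
        Folds of the stratified cross-validation in classification.
    n_random
        Degree-preserving rewired surrogates per network for sigma.
    seed
        Master seed; every stochastic stage derives its stream from it.
    """

    kde_points: int = 512
    density_range: str | tuple[int, int, int] = "auto"
    small_world_floor: float = 1.1
    nbs_edge_p: float = 0.001
    nbs_permutations: int = 10000
    nbs_alpha: float = 0.05
    covariates: Sequence[str] = ("age", "gender")
    cv_folds: int = 10
    n_random: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kde_points < 2:
            raise ValueError(f"kde_points must be >= 2, got {self.kde_points}")
        if not (0 < self.nbs_edge_p < 1):
            raise ValueError(f"nbs_edge_p must be in (0,1), got {self.nbs_edge_p}")
        if not (0 < self.nbs_alpha < 1):
            raise ValueError(f"nbs_alpha must be in (0,1), got {self.nbs_alpha}")
        if self.nbs_permutations < 1:
            raise ValueError("nbs_permutations must be positive")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.small_world_floor <= 0:
            raise ValueError("small_world_floor must be positive")
        if self.density_range != "auto":
            k_min, k_max, step = self.density_range
            if not (0 < k_min <= k_max < 100) or step < 1:
                raise ValueError(f"invalid density_range {self.density_range}")
        self.covariates = list(self.covariates)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "density_range" in raw and isinstance(raw["density_range"], list):
            raw["density_range"] = tuple(raw["density_range"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        if isinstance(d["density_range"], tuple):
            d["density_range"] = list(d["density_range"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
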