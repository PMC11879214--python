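"""Monte-Carlo validation on the synthetic benchmark designs.

Repeatedly generates a design (D1/D2/D3), runs the full pipeline with
automatic window geometry and tabulates the selected cluster number across
replicates — one row of the validation contingency matrix.  Geometry scale
factors reproduce the window-parameter sensitivity experiments (halved steps,
1.5x window sides, 1.5x steps).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pipeline import EffectProfileClusterer
from .synthetic import SyntheticSpec, generate_dataset

__all__ = ["ValidationRow", "run_validation"]

_TRUE_K = {"D1": 1, "D2": 2, "D3": 3}


@dataclass
class ValidationRow:
    """Distribution of selected cluster numbers for one design."""

    design: str
    n_datasets: int
    counts: dict[int, int]
    failures: int
    step_scale: float = 1.0
    side_scale: float = 1.0

    @property
    def true_k(self) -> int:
        return _TRUE_K[self.design]

    @property
    def n_correct(self) -> int:
        return self.counts.get(self.true_k, 0)

    @property
    def frac_correct(self) -> float:
        return self.n_correct / self.n_datasets if self.n_datasets else float("nan")

    def to_series(self, kmax: int = 5) -> pd.Series:
        s = pd.Series({k: self.counts.get(k, 0) for k in range(1, kmax + 1)})
        s.name = self.design
        return s


def run_validation(
    design: str,
    n_datasets: int,
    seed: int | None = None,
    n_target: int = 20,
    alpha: float = 1e-3,
    nref: int = 2000,
    step_scale: float = 1.0,
    side_scale: float = 1.0,
    smoothing_width: float = 0.05,
    min_class_count: int = 5,
) -> ValidationRow:
    """Run the pipeline over ``n_datasets`` replicates of one design.

    Replicate seeds (data generation and reference draws) are spawned
    deterministically from ``seed``, so results are reproducible and
    independent of any parallel execution order.
    """
    if design not in _TRUE_K:
        raise ValueError(f"design must be one of {sorted(_TRUE_K)}")
    counts: dict[int, int] = {}
    failures = 0
    ss = np.random.SeedSequence(seed)
    for child in ss.spawn(n_datasets):
        data_seed, ref_seed = (int(s) for s in child.generate_state(2) % (2**31))
        ds = generate_dataset(
            SyntheticSpec(design=design, smoothing_width=smoothing_width, seed=data_seed)
        )
        try:
            model = EffectProfileClusterer(
                n_target=n_target,
                min_class_count=min_class_count,
                alpha=alpha,
                nref=nref,
                step_scale=step_scale,
                side_scale=side_scale,
                random_state=ref_seed,
            ).fit(ds.table)
        except ValueError:
            failures += 1
            continue
        k = model.k_final_
        counts[k] = counts.get(k, 0) + 1
    return ValidationRow(
        design=design,
        n_datasets=n_datasets,
        counts=counts,
        failures=failures,
        step_scale=step_scale,
        side_scale=side_scale,
    )
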