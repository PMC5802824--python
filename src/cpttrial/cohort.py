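"""Virtual cohort generation: space-filling designs over the NF1 ranges.

Multi-decade parameters are sampled on a log10 scale; the default design
is a seeded scrambled Sobol' sequence, with latin-hypercube and plain
random fallbacks.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import qmc

from cpttrial.model import PARAM_BOUNDS, PARAM_NAMES

__all__ = [
    "CohortDesignSpec",
    "default_ranges",
    "default_scales",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]

#: Parameters spanning multiple decades are sampled logarithmically.
LOG_SCALE_PARAMS = ("A_f0", "F_4", "P_mf", "G_gvc")

DESIGNS = ("uniform_lowdiscrepancy", "latin_hypercube", "random")


def default_ranges() -> dict[str, tuple[float, float]]:
    """Inclusive (low, high) sampling bounds per parameter."""
    return dict(PARAM_BOUNDS)


def default_scales() -> dict[str, str]:
    """Sampling scale per parameter: ``log10`` for multi-decade ranges."""
    return {
        name: ("log10" if name in LOG_SCALE_PARAMS else "linear")
        for name in PARAM_NAMES
    }


@dataclass(frozen=True)
class CohortDesignSpec:
    n: int
    ranges: Mapping[str, tuple[float, float]] = field(default_factory=default_ranges)
    scales: Mapping[str, str] = field(default_factory=default_scales)
    design: str = "uniform_lowdiscrepancy"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"cohort size must be >= 1, got {self.n}")
        if self.design not in DESIGNS:
            raise ValueError(f"unknown design {self.design!r}; choose from {DESIGNS}")
        for name in PARAM_NAMES:
            low, high = self.ranges[name]
            if low > high:
                raise ValueError(f"inverted range for {name}: ({low}, {high})")
            if self.scales[name] == "log10" and low <= 0 and low < high:
                raise ValueError(f"log10 scale needs positive bounds for {name}")


def _unit_samples(spec: CohortDesignSpec) -> np.ndarray:
    """n x 8 samples in the unit hypercube according to the chosen design."""
    d = len(PARAM_NAMES)
    rng_seed = spec.seed
    if spec.design == "uniform_lowdiscrepancy":
        sampler = qmc.Sobol(d=d, scramble=True, seed=rng_seed)
        with warnings.catch_warnings():
            # arbitrary n is intentional; balance loss is acceptable here
            warnings.simplefilter("ignore", UserWarning)
            return sampler.random(spec.n)
    if spec.design == "latin_hypercube":
        sampler = qmc.LatinHypercube(d=d, seed=rng_seed)
        return sampler.random(spec.n)
    rng = np.random.default_rng(rng_seed)
    return rng.random((spec.n, d))


def generate_cohort(spec: CohortDesignSpec) -> pd.DataFrame:
    """Generate ``spec.n`` unique in-range parameter vectors.

    Returns a DataFrame with a ``subject_id`` column (``S0001`` ...)
    followed by the eight parameter columns.  Deterministic given
    ``spec.seed``.
    """
    unit = _unit_samples(spec)
    columns: dict[str, np.ndarray] = {}
    for j, name in enumerate(PARAM_NAMES):
        low, high = spec.ranges[name]
        u = unit[:, j]
        if low == high:
            columns[name] = np.full(spec.n, low)
        elif spec.scales[name] == "log10":
            lo, hi = np.log10(low), np.log10(high)
            columns[name] = 10.0 ** (lo + u * (hi - lo))
        else:
            columns[name] = low + u * (high - low)

    df = pd.DataFrame(columns)
    if df.duplicated().any():
        raise RuntimeError("design produced duplicate parameter vectors")
    df.insert(0, "subject_id", [f"S{i + 1:04d}" for i in range(spec.n)])
    return df


def write_cohort(df: pd.DataFrame, path: str | Path, spec: CohortDesignSpec) -> None:
    """Write the cohort CSV plus a JSON sidecar recording the design spec."""
    path = Path(path)
    df.to_csv(path, index=False)
    sidecar = {
        "n": spec.n,
        "design": spec.design,
        "seed": spec.seed,
        "ranges": {k: list(v) for k, v in spec.ranges.items()},
        "scales": dict(spec.scales),
        "numpy_version": np.__version__,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort CSV written by :func:`write_cohort`."""
    df = pd.read_csv(path)
    missing = [c for c in ("subject_id", *PARAM_NAMES) if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file {path} missing columns: {missing}")
    if df["subject_id"].duplicated().any():
        raise ValueError(f"cohort file {path} contains duplicate subject ids")
    return df[["subject_id", *PARAM_NAMES]]
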