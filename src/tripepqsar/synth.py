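"""Synthetic tripeptide datasets with known ground truth.

The generator emulates the statistical structure of the study data: random
tripeptide sequences, an activity that is a sparse linear function of the
autoscaled encoded variables plus Gaussian noise, optionally passed through
a power-of-ten link (so that a log10 transform restores linearity, mirroring
the nonlinearity of the raw FRAP activities), and optional planted outliers
shifted in response-SD units.  Ground truth records which variables carry
signal and which samples are outliers, so recovery by the outlier and
variable-selection stages can be scored exactly.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .pls import autoscale
from .scales import AMINO_ACIDS, EncodedDataset, encode_dataset, get_scale


@dataclass(frozen=True)
class SyntheticSpec:
    """Stated world for one synthetic dataset."""

    n_peptides: int = 100
    scales: Sequence[str] = ("Z-scale", "VHSE")
    n_signal_variables: int = 5
    effect_size: float = 1.0          # coefficient SD, scaled-variable units
    noise_sd: float = 0.3             # residual SD on the linear scale
    outlier_indices: Sequence[int] = ()
    outlier_shift: float = 0.0        # in response-SD units
    response_link: str = "identity"   # identity | exponential (10**linear)
    seed: int = 0

    def __post_init__(self):
        if self.n_peptides < 2:
            raise ValueError("need at least 2 peptides")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.response_link not in ("identity", "exponential"):
            raise ValueError(f"unknown response_link {self.response_link!r}")
        if any(not 0 <= i < self.n_peptides for i in self.outlier_indices):
            raise ValueError("outlier_indices out of range")


@dataclass
class GroundTruth:
    signal_variables: list[str]
    coefficients: np.ndarray
    outlier_ids: list
    linear_response: np.ndarray = field(repr=False, default=None)


def generate(spec: SyntheticSpec):
    """Generate an (EncodedDataset, GroundTruth) pair from a spec.

    Sequences are drawn uniformly over the 20-letter alphabet; the linear
    response is built on the autoscaled X so ``effect_size`` and
    ``noise_sd`` share one unit system.  Fully reproducible by seed.
    """
    rng = np.random.default_rng(spec.seed)
    seqs = [
        "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=3))
        for _ in range(spec.n_peptides)
    ]
    scales = [get_scale(name) for name in spec.scales]
    base = encode_dataset(seqs, np.zeros(spec.n_peptides), scales,
                          sample_ids=list(range(spec.n_peptides)))
    p = base.n_variables
    if not 1 <= spec.n_signal_variables <= p:
        raise ValueError(
            f"n_signal_variables must be in 1..{p} for these scales"
        )
    Xs, _, _ = autoscale(base.X, base.y)
    signal = np.sort(rng.choice(p, size=spec.n_signal_variables, replace=False))
    beta = rng.normal(0.0, spec.effect_size, size=spec.n_signal_variables)
    linear = Xs[:, signal] @ beta + rng.normal(0.0, spec.noise_sd,
                                               size=spec.n_peptides)
    y = linear.copy()
    if spec.outlier_indices:
        shift = spec.outlier_shift * (y.std(ddof=0) or 1.0)
        for i in spec.outlier_indices:
            y[i] += shift
    if spec.response_link == "exponential":
        y = 10.0 ** y
    data = EncodedDataset(
        X=base.X, variable_labels=base.variable_labels,
        sample_ids=base.sample_ids, y=y, sequences=seqs,
    )
    truth = GroundTruth(
        signal_variables=[base.variable_labels[j] for j in signal],
        coefficients=beta,
        outlier_ids=[base.sample_ids[i] for i in spec.outlier_indices],
        linear_response=linear,
    )
    return data, truth


def write_fixture(data: EncodedDataset, path) -> None:
    """Write sequences/activities in the same tabular format as the bundled
    datasets, so synthetic sets flow through the identical loading path."""
    lines = ["no\tsequence\tactivity"]
    for i, (seq, act) in enumerate(zip(data.sequences, data.y), start=1):
        lines.append(f"{i}\t{seq}\t{float(act)!r}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
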