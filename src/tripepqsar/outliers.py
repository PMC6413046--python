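"""MPA-based outlier detection and iterative one-by-one elimination.

For the current dataset, 1000 random sub-datasets of 80% of the samples are
drawn (bootstrap resampling in sample space); each sub-dataset gets its own
autoscaled PLS model (component count fixed per iteration from a full-data
CV), and every out-of-subset sample's prediction error is recorded.  A
sample's profile value is its mean out-of-subset error — signed by default,
so a genuine outlier shows up as a systematic bias while ordinary samples
scatter around zero.  Samples outside mean +/- 3 x SD of the profile are
flagged, the worst one is removed, and the whole procedure repeats until no
sample is flagged.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._kernels import mpa_error_profile
from .pls import CVScheme, DEFAULT_MAX_COMPONENTS, cross_validate, select_components
from .scales import EncodedDataset


class ResamplingCoverageError(RuntimeError):
    """A sample was never left out of any sub-dataset; increase n_sub."""


@dataclass(frozen=True)
class OutlierDetection:
    flagged: list
    candidate: Optional[object]
    mean: float
    sd: float

    @property
    def boundary_low(self) -> float:
        return self.mean - 3.0 * self.sd

    @property
    def boundary_high(self) -> float:
        return self.mean + 3.0 * self.sd


@dataclass
class OutlierIteration:
    """One elimination round: per-sample errors, 3-sigma band, decision."""

    sample_ids: list
    per_sample_error: np.ndarray
    n_components: int
    detection: OutlierDetection
    eliminated: Optional[object]

    @property
    def boundary_low(self) -> float:
        return self.detection.boundary_low

    @property
    def boundary_high(self) -> float:
        return self.detection.boundary_high

    def to_dict(self) -> dict:
        return {
            "sample_ids": list(self.sample_ids),
            "per_sample_error": [float(e) for e in self.per_sample_error],
            "n_components": int(self.n_components),
            "boundary_low": float(self.boundary_low),
            "boundary_high": float(self.boundary_high),
            "flagged": list(self.detection.flagged),
            "eliminated": self.eliminated,
        }


@dataclass
class OutlierReport:
    iterations: list = field(default_factory=list)
    removed_sequence: list = field(default_factory=list)
    final_dataset: EncodedDataset = None

    def to_dict(self) -> dict:
        return {
            "removed_sequence": list(self.removed_sequence),
            "n_iterations": len(self.iterations),
            "iterations": [it.to_dict() for it in self.iterations],
        }


def sample_error_profile(
    data: EncodedDataset,
    n_sub: int = 1000,
    frac: float = 0.8,
    seed: int = 0,
    cv: CVScheme = CVScheme(),
    n_components: int | None = None,
    max_components: int = DEFAULT_MAX_COMPONENTS,
    statistic: str = "signed",
    replace: bool = True,
    rng: np.random.Generator | None = None,
):
    """Mean out-of-subset prediction error for each sample.

    ``statistic`` selects the signed mean error (default; an outlier is a
    sample the sub-models mispredict with a systematic bias) or the mean
    absolute error.  ``replace`` controls whether the 80% sub-datasets are
    bootstrap draws (default) or subsets without replacement.  Returns
    ``(profile, n_components)``; the component count is chosen once on the
    full data by cross-validation unless given.
    """
    n = data.n_samples
    if n < 10:
        raise ValueError("outlier analysis needs at least 10 samples")
    if not 0.0 < frac < 1.0:
        raise ValueError("frac must be in (0, 1)")
    if statistic not in ("signed", "absolute"):
        raise ValueError(f"unknown error statistic {statistic!r}")
    m = int(np.floor(frac * n))
    if m < 2 or m >= n:
        raise ValueError(f"subset size {m} leaves no held-out samples")
    if n_components is None:
        q2 = cross_validate(data.X, data.y, cv, max_components)
        n_components = select_components(q2)
    if rng is None:
        rng = np.random.default_rng(seed)
    if replace:
        subsets = rng.integers(0, n, size=(n_sub, m))
    else:
        # one permutation per sub-dataset; first m entries form the subset
        subsets = np.argsort(rng.random((n_sub, n)), axis=1)[:, :m]
    subsets = np.ascontiguousarray(subsets, dtype=np.int64)
    signed, absolute, cnt = mpa_error_profile(
        data.X, data.y, subsets, n_components
    )
    if np.any(cnt == 0):
        bad = [data.sample_ids[i] for i in np.flatnonzero(cnt == 0)]
        raise ResamplingCoverageError(
            f"samples {bad} were never left out of a sub-dataset; "
            f"increase n_sub (got {n_sub})"
        )
    err_sum = signed if statistic == "signed" else absolute
    return err_sum / cnt, n_components


def detect_outlier(profile) -> OutlierDetection:
    """Apply the three-sigma rule to an error profile.

    Samples outside mean +/- 3 x SD are flagged; the flagged sample with
    the largest deviation from the mean is the elimination candidate.  (For
    a nonnegative absolute-error profile only the upper boundary can flag
    in practice.)
    """
    profile = np.asarray(profile, dtype=float)
    if profile.size == 0:
        raise ValueError("empty error profile")
    mean = float(profile.mean())
    sd = float(profile.std(ddof=0))
    dev = np.abs(profile - mean)
    flagged = np.flatnonzero(dev > 3.0 * sd)
    candidate = None
    if flagged.size:
        candidate = int(flagged[np.argmax(dev[flagged])])
    return OutlierDetection(
        flagged=[int(i) for i in flagged], candidate=candidate,
        mean=mean, sd=sd,
    )


def eliminate_outliers(
    data: EncodedDataset,
    n_sub: int = 1000,
    frac: float = 0.8,
    seed: int = 0,
    cv: CVScheme = CVScheme(),
    max_components: int = DEFAULT_MAX_COMPONENTS,
    statistic: str = "signed",
    replace: bool = True,
) -> OutlierReport:
    """Repeat profile -> detect -> remove-worst until no sample is flagged.

    A single seeded generator drives all sub-dataset draws, so the full
    elimination trajectory is reproducible.
    """
    report = OutlierReport()
    current = data
    rng = np.random.default_rng(seed)
    while True:
        profile, ncomp = sample_error_profile(
            current, n_sub=n_sub, frac=frac, cv=cv,
            max_components=max_components, statistic=statistic,
            replace=replace, rng=rng,
        )
        det = detect_outlier(profile)
        eliminated = None
        if det.candidate is not None:
            eliminated = current.sample_ids[det.candidate]
        report.iterations.append(OutlierIteration(
            sample_ids=list(current.sample_ids),
            per_sample_error=profile,
            n_components=ncomp,
            detection=OutlierDetection(
                flagged=[current.sample_ids[i] for i in det.flagged],
                candidate=eliminated, mean=det.mean, sd=det.sd,
            ),
            eliminated=eliminated,
        ))
        if eliminated is None:
            break
        report.removed_sequence.append(eliminated)
        keep = [i for i in range(current.n_samples) if i != det.candidate]
        current = current.subset_samples(keep)
    report.final_dataset = current
    return report
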