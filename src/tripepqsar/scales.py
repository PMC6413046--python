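"""Amino-acid descriptor scales and tripeptide encoding.

A descriptor scale maps each of the 20 standard residues to ``k`` real-valued
physicochemical properties.  A tripeptide is encoded by concatenating the
property vectors of its N-terminal, middle and C-terminal residues, giving
``3k`` variables labelled ``N-<scale>-1..k``, ``M-<scale>-1..k``,
``C-<scale>-1..k``.  The sixteen bundled scales, integrated in the canonical
registry order, yield the 306-variable matrix V1..V306 used throughout the
pipeline.

Scale constants are shipped as tab-separated data files with a citation
header; files whose header says ``provenance: synthetic`` are stand-ins
derived by PCA of computed amino-acid descriptors because the originally
published table was not available for transcription (see docs/methods.md).
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: canonical integration order; frozen so variable indices V1-V306 are stable
REGISTRY_ORDER = (
    "Z-scale", "5Z-scale", "DPPS", "MS-WHIM1", "MS-WHIM2", "ISA-ECI",
    "VHSE", "FASGAI", "VSW", "E-scale", "T-scale", "ST-scale", "V-scale",
    "G-scale", "HESH", "HSEHPCSV",
)

_SCALE_FILES = {
    "Z-scale": "z_scale.tsv", "5Z-scale": "z5_scale.tsv", "DPPS": "dpps.tsv",
    "MS-WHIM1": "ms_whim1.tsv", "MS-WHIM2": "ms_whim2.tsv",
    "ISA-ECI": "isa_eci.tsv", "VHSE": "vhse.tsv", "FASGAI": "fasgai.tsv",
    "VSW": "vsw.tsv", "E-scale": "e_scale.tsv", "T-scale": "t_scale.tsv",
    "ST-scale": "st_scale.tsv", "V-scale": "v_scale.tsv",
    "G-scale": "g_scale.tsv", "HESH": "hesh.tsv", "HSEHPCSV": "hsehpcsv.tsv",
}

#: short tokens used in variable labels (matches the in-field naming, e.g.
#: N-Z-1, C-Z5-5, N-G-7, C-HSEHPCSV-9)
LABEL_TOKEN = {
    "Z-scale": "Z", "5Z-scale": "Z5", "DPPS": "DPPS", "MS-WHIM1": "MSW1",
    "MS-WHIM2": "MSW2", "ISA-ECI": "ISAECI", "VHSE": "VHSE",
    "FASGAI": "FASGAI", "VSW": "VSW", "E-scale": "E", "T-scale": "T",
    "ST-scale": "ST", "V-scale": "V", "G-scale": "G", "HESH": "HESH",
    "HSEHPCSV": "HSEHPCSV",
}

EXPECTED_K = {
    "Z-scale": 3, "5Z-scale": 5, "DPPS": 10, "MS-WHIM1": 3, "MS-WHIM2": 3,
    "ISA-ECI": 2, "VHSE": 8, "FASGAI": 6, "VSW": 9, "T-scale": 5,
    "ST-scale": 8, "E-scale": 5, "V-scale": 3, "G-scale": 8, "HESH": 12,
    "HSEHPCSV": 12,
}


class ScaleRegistryError(KeyError):
    """Unknown scale identifier."""


class ScaleDataError(ValueError):
    """Bundled scale file failed validation."""


class EncodingError(ValueError):
    """Invalid peptide sequence for encoding."""


@dataclass(frozen=True)
class DescriptorScale:
    """A named amino-acid property table (20 residues x k properties)."""

    name: str
    k: int
    values: Mapping[str, tuple]
    source: str
    provenance: str = "transcribed"
    #: 20 x k lookup matrix in AMINO_ACIDS order
    matrix: np.ndarray = field(repr=False, default=None)

    def vector(self, residue: str) -> np.ndarray:
        try:
            return np.asarray(self.values[residue], dtype=float)
        except KeyError:
            raise EncodingError(
                f"unknown residue {residue!r}; expected one of "
                f"{''.join(AMINO_ACIDS)}"
            ) from None

    @property
    def token(self) -> str:
        return LABEL_TOKEN.get(self.name, self.name)


def _data_bytes(fname: str) -> bytes:
    return (resources.files("tripepqsar") / "data" / "scales" / fname).read_bytes()


def _load_scale_file(fname: str) -> DescriptorScale:
    raw = _data_bytes(fname)
    expected = json.loads(_data_bytes("checksums.json"))
    digest = hashlib.sha256(raw).hexdigest()
    if expected.get(fname) != digest:
        raise ScaleDataError(f"checksum mismatch for scale data file {fname}")
    meta = {}
    body = []
    for line in raw.decode().splitlines():
        if line.startswith("#"):
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = val.strip()
        elif line.strip():
            body.append(line.split("\t"))
    header, rows = body[0], body[1:]
    k = int(meta["k"])
    if len(header) != k + 1 or len(rows) != 20:
        raise ScaleDataError(f"{fname}: expected 20 x {k} table")
    values = {}
    for row in rows:
        aa = row[0]
        if aa not in _AA_INDEX or aa in values:
            raise ScaleDataError(f"{fname}: bad residue row {aa!r}")
        vec = tuple(float(v) for v in row[1:])
        if len(vec) != k:
            raise ScaleDataError(f"{fname}: row {aa} has {len(vec)} values")
        values[aa] = vec
    matrix = np.asarray([values[a] for a in AMINO_ACIDS], dtype=float)
    return DescriptorScale(
        name=meta["name"], k=k, values=values, source=meta.get("source", ""),
        provenance=meta.get("provenance", "transcribed"), matrix=matrix,
    )


_CACHE: dict[str, DescriptorScale] = {}


def get_scale(name: str) -> DescriptorScale:
    """Return a bundled descriptor scale by registry identifier."""
    if name not in _SCALE_FILES:
        raise ScaleRegistryError(
            f"unknown scale {name!r}; valid identifiers: "
            + ", ".join(REGISTRY_ORDER)
        )
    if name not in _CACHE:
        scale = _load_scale_file(_SCALE_FILES[name])
        if scale.name != name or scale.k != EXPECTED_K[name]:
            raise ScaleDataError(f"scale file for {name} is inconsistent")
        _CACHE[name] = scale
    return _CACHE[name]


def all_scales() -> tuple[DescriptorScale, ...]:
    """The full 16-scale registry in canonical integration order."""
    return tuple(get_scale(n) for n in REGISTRY_ORDER)


def _positions(length: int) -> list[str]:
    if length == 3:
        return ["N", "M", "C"]
    # generic positional labels; only the tripeptide path is validated
    # against the study datasets
    return [f"P{i + 1}" for i in range(length)]


def _check_sequence(seq: str, length: int | None = 3) -> None:
    if not isinstance(seq, str) or (length is not None and len(seq) != length):
        raise EncodingError(f"expected a tripeptide, got {seq!r}")
    for pos, aa in enumerate(seq):
        if aa not in _AA_INDEX:
            raise EncodingError(
                f"sequence {seq!r} has unsupported residue {aa!r} at "
                f"position {pos + 1}"
            )


def peptide_labels(scale: DescriptorScale, length: int = 3) -> list[str]:
    return [
        f"{pos}-{scale.token}-{j + 1}"
        for pos in _positions(length)
        for j in range(scale.k)
    ]


def encode_peptide(sequence: str, scale: DescriptorScale):
    """Encode one peptide with one scale.

    Returns ``(values, labels)`` where values has length ``len(sequence)*k``
    ordered N-terminal block first, then middle, then C-terminal.
    """
    _check_sequence(sequence, None if len(sequence) >= 2 else 3)
    if len(sequence) < 2:
        raise EncodingError(f"peptide too short: {sequence!r}")
    values = np.concatenate([scale.vector(aa) for aa in sequence])
    return values, peptide_labels(scale, len(sequence))


@dataclass
class EncodedDataset:
    """Encoded peptide set: X matrix, labels, sample ids and response y."""

    X: np.ndarray
    variable_labels: list[str]
    sample_ids: list
    y: np.ndarray
    sequences: list[str] | None = None

    def __post_init__(self):
        self.X = np.ascontiguousarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n, p = self.X.shape
        if len(self.y) != n or len(self.sample_ids) != n:
            raise ValueError("X, y and sample_ids lengths disagree")
        if len(self.variable_labels) != p:
            raise ValueError("variable_labels length disagrees with X")
        if len(set(self.variable_labels)) != p:
            raise ValueError("variable_labels are not unique")
        if not np.isfinite(self.X).all() or not np.isfinite(self.y).all():
            raise ValueError("encoded data contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_variables(self) -> int:
        return self.X.shape[1]

    def subset_samples(self, keep: Sequence[int]) -> "EncodedDataset":
        keep = np.asarray(keep, dtype=int)
        return EncodedDataset(
            X=self.X[keep],
            variable_labels=list(self.variable_labels),
            sample_ids=[self.sample_ids[i] for i in keep],
            y=self.y[keep],
            sequences=None if self.sequences is None
            else [self.sequences[i] for i in keep],
        )

    def drop_samples(self, ids: Iterable) -> "EncodedDataset":
        drop = set(ids)
        keep = [i for i, s in enumerate(self.sample_ids) if s not in drop]
        if len(keep) != self.n_samples - len(drop):
            missing = drop - set(self.sample_ids)
            raise KeyError(f"sample ids not present: {sorted(missing)}")
        return self.subset_samples(keep)

    def select_variables(self, which) -> "EncodedDataset":
        if len(which) and isinstance(which[0], str):
            pos = {l: j for j, l in enumerate(self.variable_labels)}
            idx = [pos[l] for l in which]
        else:
            idx = list(which)
        return EncodedDataset(
            X=self.X[:, idx],
            variable_labels=[self.variable_labels[j] for j in idx],
            sample_ids=list(self.sample_ids),
            y=self.y.copy(),
            sequences=None if self.sequences is None else list(self.sequences),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.variable_labels)
        df.insert(0, "sample_id", self.sample_ids)
        df["activity"] = self.y
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def encode_dataset(
    sequences: Sequence[str],
    y: Sequence[float],
    scales: Sequence[DescriptorScale] | None = None,
    sample_ids: Sequence | None = None,
) -> EncodedDataset:
    """Encode peptides with an ordered list of scales into one X-matrix.

    Column blocks follow the given scale order; with the default full
    registry the columns correspond to the canonical integrated variables
    V1..V306.
    """
    if scales is None:
        scales = all_scales()
    scales = list(scales)
    if not scales:
        raise ValueError("need at least one descriptor scale")
    sequences = list(sequences)
    if not sequences:
        raise ValueError("need at least one sequence")
    y = np.asarray(list(y), dtype=float)
    if len(y) != len(sequences):
        raise ValueError(
            f"{len(sequences)} sequences but {len(y)} responses"
        )
    length = len(sequences[0])
    for seq in sequences:
        _check_sequence(seq, length)
    codes = np.asarray(
        [[_AA_INDEX[aa] for aa in seq] for seq in sequences], dtype=int
    )
    blocks = []
    labels: list[str] = []
    for scale in scales:
        # (n, L, k) lookup -> per-position blocks concatenated N..C
        block = scale.matrix[codes]
        blocks.append(block.reshape(len(sequences), length * scale.k))
        labels.extend(peptide_labels(scale, length))
    if sample_ids is None:
        sample_ids = list(sequences)
    return EncodedDataset(
        X=np.hstack(blocks), variable_labels=labels,
        sample_ids=list(sample_ids), y=y, sequences=sequences,
    )
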