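"""The two study datasets of antioxidant tripeptides.

FTC: 214 His/Tyr/Trp-containing tripeptides with relative antioxidant
activities from the ferric thiocyanate assay (control = 1.0).

FRAP: 172 tripeptides derived from beta-lactoglobulin with log-transformed
ferric-reducing antioxidant power activities; 14 inactive peptides
(rows 159-172) have no activity and are dropped before modeling.

Both tables ship as tab-separated fixtures validated by checksum; the same
loader accepts user-supplied files in the identical format.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import numpy as np

from .scales import DescriptorScale, EncodedDataset, encode_dataset

_FIXTURE_SHA256 = {
    "ftc.tsv": "73a0f3d10615ffdade77a25d6f44edfedfbae7577ddc452b3540f3834201fce1",
    "frap.tsv": "94a57cc73e2374ceb34e05b1d4103efcef5857eba1d59c4caca299530456d303",
}

_VALID_AA = set("ACDEFGHIKLMNPQRSTVWY")


class DataIntegrityError(ValueError):
    """Fixture failed its checksum or structural validation."""


@dataclass(frozen=True)
class PeptideRecord:
    row_number: int
    sequence: str
    activity: Optional[float]


@dataclass
class PeptideDataset:
    """A named peptide/activity table keyed by printed row number."""

    name: str
    records: list[PeptideRecord]
    log_transformed: bool = False

    def __len__(self) -> int:
        return len(self.records)

    @property
    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    @property
    def row_numbers(self) -> list[int]:
        return [r.row_number for r in self.records]

    @property
    def activities(self) -> np.ndarray:
        vals = [r.activity for r in self.records]
        if any(v is None for v in vals):
            raise ValueError(
                f"{self.name}: dataset still contains records without an "
                "activity; load with drop_inactive=True for modeling"
            )
        return np.asarray(vals, dtype=float)

    def encode(
        self, scales: Sequence[DescriptorScale] | None = None
    ) -> EncodedDataset:
        """Encode into an X-matrix; sample ids are the printed row numbers."""
        return encode_dataset(
            self.sequences, self.activities, scales,
            sample_ids=self.row_numbers,
        )


def _parse_table(text: str, name: str) -> list[PeptideRecord]:
    lines = [l for l in text.splitlines() if l.strip()]
    if lines[0].split("\t") != ["no", "sequence", "activity"]:
        raise DataIntegrityError(f"{name}: unexpected fixture header")
    records = []
    for line in lines[1:]:
        no, seq, act = line.split("\t")
        if set(seq) - _VALID_AA or len(seq) != 3:
            raise DataIntegrityError(f"{name}: bad sequence {seq!r}")
        records.append(
            PeptideRecord(int(no), seq, float(act) if act else None)
        )
    rows = [r.row_number for r in records]
    if rows != list(range(1, len(records) + 1)):
        raise DataIntegrityError(f"{name}: row numbers are not 1..n")
    return records


def _load_fixture(fname: str) -> list[PeptideRecord]:
    raw = (resources.files("tripepqsar") / "data" / fname).read_bytes()
    if hashlib.sha256(raw).hexdigest() != _FIXTURE_SHA256[fname]:
        raise DataIntegrityError(f"checksum mismatch for fixture {fname}")
    return _parse_table(raw.decode(), fname)


def load_peptide_table(path, name: str = "user") -> PeptideDataset:
    """Load a user-supplied table in the fixture format (no\\tseq\\tactivity)."""
    with open(path) as fh:
        return PeptideDataset(name=name, records=_parse_table(fh.read(), name))


def load_ftc() -> PeptideDataset:
    """The 214-peptide ferric thiocyanate dataset (relative activities)."""
    records = _load_fixture("ftc.tsv")
    if len(records) != 214 or any(r.activity is None or r.activity < 0
                                  for r in records):
        raise DataIntegrityError("ftc fixture failed validation")
    return PeptideDataset(name="FTC", records=records)

def load_frap(drop_inactive: bool = True) -> PeptideDataset:
    """The FRAP dataset (activities already log-transformed as printed).

    With ``drop_inactive`` the 14 peptides without a measurable activity are
    removed, leaving the 158 samples used for modeling.
    """
    records = _load_fixture("frap.tsv")
    inactive = [r for r in records if r.activity is None]
    if len(records) != 172 or len(inactive) != 14:
        raise DataIntegrityError("frap fixture failed validation")
    if drop_inactive:
        records = [r for r in records if r.activity is not None]
    return PeptideDataset(name="FRAP", records=records, log_transformed=True)


def log_transform(activities) -> np.ndarray:
    """Base-10 logarithm of positive activities (monotone, order-preserving).

    Zero or negative activities are rejected, mirroring the removal of
    inactive peptides before modeling.
    """
    arr = np.asarray(activities, dtype=float)
    if not np.all(arr > 0):
        raise ValueError("log transform requires strictly positive activities")
    return np.log10(arr)
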