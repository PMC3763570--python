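"""Labeled datasets: sequences, optional profiles, and location labels."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .features import FeatureConfig, descriptor_vector
from .profiles import ProteinRecord, StandardizedProfile, load_profiles, read_fasta
from .properties import NormalizedPropertyTable


class DatasetError(ValueError):
    """Raised for inconsistent dataset inputs."""


@dataclass
class LabeledDataset:
    """Protein records with location labels and (optionally) profiles."""

    records: list[ProteinRecord]
    labels: list[str]
    profiles: list[StandardizedProfile] | None = None

    def __post_init__(self) -> None:
        if len(self.records) != len(self.labels):
            raise DatasetError(
                f"{len(self.records)} records but {len(self.labels)} labels"
            )
        if self.profiles is not None and len(self.profiles) != len(self.records):
            raise DatasetError("profiles and records differ in length")
        ids = [r.identifier for r in self.records]
        if len(set(ids)) != len(ids):
            raise DatasetError("duplicate identifiers in dataset")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def identifiers(self) -> list[str]:
        return [r.identifier for r in self.records]

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.labels))

    @property
    def min_length(self) -> int:
        return min(r.length for r in self.records)

    def feature_matrix(
        self, props: NormalizedPropertyTable, config: FeatureConfig
    ) -> np.ndarray:
        """Descriptor matrix over the dataset's profiles (one-hot if absent)."""
        profiles = self.profiles
        if profiles is None:
            profiles = load_profiles(self.records, None)
        return np.vstack(
            [descriptor_vector(p, props, config).q for p in profiles]
        )

    @classmethod
    def from_paths(
        cls, fasta_path, labels_path, pssm_dir=None
    ) -> "LabeledDataset":
        """Load from a FASTA file, a labels TSV (identifier<TAB>label) and an
        optional PSSM directory (``<identifier>.pssm`` files)."""
        records = read_fasta(str(fasta_path))
        label_map: dict[str, str] = {}
        for lineno, line in enumerate(
            Path(labels_path).read_text(encoding="utf-8").splitlines(), start=1
        ):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise DatasetError(
                    f"{labels_path}: line {lineno}: expected identifier<TAB>label"
                )
            if parts[0] in label_map:
                raise DatasetError(
                    f"{labels_path}: line {lineno}: duplicate identifier {parts[0]}"
                )
            label_map[parts[0]] = parts[1]
        missing = [r.identifier for r in records if r.identifier not in label_map]
        if missing:
            raise DatasetError(f"no label for identifiers: {missing}")
        labels = [label_map[r.identifier] for r in records]
        profiles = load_profiles(records, pssm_dir)
        return cls(records, labels, profiles)


def write_labels_tsv(dataset: LabeledDataset, path) -> None:
    """Write an identifier<TAB>label table."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec, label in zip(dataset.records, dataset.labels):
            fh.write(f"{rec.identifier}\t{label}\n")
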