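"""Product label manifests: declared ingredient lists plus metadata."""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .taxonomy import normalize_binomial

SOURCE_TYPES = ("IN_HOUSE", "REGISTERED")
DOSAGE_FORMS = ("POWDER", "TABLET", "CAPSULE")


@dataclass(frozen=True)
class FormulationLabel:
    """One product's declared composition and metadata.

    ``declared_species`` holds canonical binomials (normalized, duplicates
    forbidden); herbal products on the audited list declare 1-55 species.
    """

    sample_id: str
    product_name: str
    source_type: str
    dosage_form: str
    declared_species: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.source_type not in SOURCE_TYPES:
            raise ValueError(f"invalid source_type {self.source_type!r}")
        if self.dosage_form not in DOSAGE_FORMS:
            raise ValueError(f"invalid dosage_form {self.dosage_form!r}")
        if not self.declared_species:
            raise ValueError(f"label {self.sample_id}: declared list is empty")
        normalized = tuple(normalize_binomial(s) for s in self.declared_species)
        if len(set(normalized)) != len(normalized):
            raise ValueError(f"label {self.sample_id}: duplicate declared species")
        object.__setattr__(self, "declared_species", normalized)


def write_label_manifest(labels: Iterable[FormulationLabel], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("sample_id\tproduct_name\tsource_type\tdosage_form\tdeclared_species\n")
        for lab in labels:
            fh.write(
                f"{lab.sample_id}\t{lab.product_name}\t{lab.source_type}\t"
                f"{lab.dosage_form}\t{';'.join(lab.declared_species)}\n"
            )


def read_label_manifest(path: str | Path) -> list[FormulationLabel]:
    labels: list[FormulationLabel] = []
    with Path(path).open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["sample_id", "product_name", "source_type", "dosage_form", "declared_species"]
        if header != expected:
            raise ValueError(f"{path}: unexpected manifest header {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise ValueError(f"{path}: malformed row at line {lineno}")
            sample_id, name, source, dosage, species = parts
            labels.append(
                FormulationLabel(
                    sample_id, name, source, dosage, tuple(species.split(";"))
                )
            )
    return labels
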