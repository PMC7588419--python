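"""Shared fixtures and a derandomized hypothesis profile."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from herbmark.taxonomy import Lineage, RefRecord, build_reference_index

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def _lin(family: str, genus: str, species: str, kingdom: str = "Plantae") -> Lineage:
    return Lineage(
        kingdom=kingdom,
        phylum="Tracheophyta" if kingdom == "Plantae" else "Ascomycota",
        class_="Magnoliopsida" if kingdom == "Plantae" else "Sordariomycetes",
        order=family.replace("aceae", "ales"),
        family=family,
        genus=genus,
        species=species,
    )


def _mutseq(base: str, positions: list[int]) -> str:
    """Substitute the given positions of *base* cyclically (A->C->G->T->A)."""
    nxt = {"A": "C", "C": "G", "G": "T", "T": "A"}
    arr = list(base)
    for p in positions:
        arr[p] = nxt[arr[p]]
    return "".join(arr)


@pytest.fixture(scope="session")
def tiny_refdb() -> list[RefRecord]:
    """Six ITS2-like records: two families x two genera/species plus a
    fungal contaminant, built from fixed seeds so tests are reproducible."""
    rng = np.random.default_rng(20240501)
    bases = "ACGT"
    root_a = "".join(bases[i] for i in rng.integers(0, 4, size=220))
    root_b = "".join(bases[i] for i in rng.integers(0, 4, size=240))
    fung = "".join(bases[i] for i in rng.integers(0, 4, size=230))
    gen_a1 = root_a
    gen_a2 = _mutseq(root_a, list(range(0, 220, 12)))  # ~8% diverged genus
    sp_a1x = gen_a1
    sp_a1y = _mutseq(gen_a1, list(range(3, 220, 25)))  # ~4% diverged species
    return [
        RefRecord("ITS2_Alphus_primus", "ITS2", sp_a1x,
                  _lin("Alphaceae", "Alphus", "Alphus primus")),
        RefRecord("ITS2_Alphus_secundus", "ITS2", sp_a1y,
                  _lin("Alphaceae", "Alphus", "Alphus secundus")),
        RefRecord("ITS2_Betus_tertius", "ITS2", gen_a2,
                  _lin("Alphaceae", "Betus", "Betus tertius")),
        RefRecord("ITS2_Gammus_quartus", "ITS2", root_b,
                  _lin("Gammaceae", "Gammus", "Gammus quartus")),
        RefRecord("ITS2_Gammus_quintus", "ITS2", _mutseq(root_b, list(range(5, 240, 22))),
                  _lin("Gammaceae", "Gammus", "Gammus quintus")),
        RefRecord("ITS2_Fungus_mold", "ITS2", fung,
                  _lin("Moldaceae", "Moldus", "Moldus niger", kingdom="Fungi")),
    ]


@pytest.fixture(scope="session")
def tiny_index(tiny_refdb):
    return build_reference_index(tiny_refdb, k=8)
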