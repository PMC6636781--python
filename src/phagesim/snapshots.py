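"""Genome-snapshot export: serialize sampled genomes with full gene-level
detail (category, drug, activity, strain-of-origin provenance) plus prophage
annotations, as JSON.  Deserializing reproduces the genomes exactly, so a
snapshot is a faithful record of who carries what DNA from whom."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import Gene, Genome, PhageGenotype, Prophage
from .lattice import Lattice

__all__ = ["GenomeSnapshot", "export_snapshot", "serialize", "deserialize", "snapshot_genomes"]


@dataclass(frozen=True)
class GenomeSnapshot:
    """A sample of cell genomes at one iteration.

    ``cells`` holds one entry per sampled bacterium: strain label, the
    ordered gene list (``None`` for empty/prophage-occupied slots), and the
    prophage records (genotype parameters included, so reloading rebuilds the
    exact genome objects).
    """

    iteration: int
    sample_size: int
    cells: tuple[dict, ...]


def _gene_dict(g: Optional[Gene]) -> Optional[dict]:
    if g is None:
        return None
    return {
        "gene_id": g.gene_id,
        "category": g.category,
        "drug": g.drug,
        "active": g.active,
        "provenance": g.provenance,
    }


def _prophage_dict(p: Prophage) -> dict:
    return {
        "start_locus": p.start_locus,
        "span": p.span,
        "genotype": dataclasses.asdict(p.genotype),
    }


def export_snapshot(
    lattice: Lattice, n_cells: int, rng: np.random.Generator
) -> GenomeSnapshot:
    """Uniformly sample ``n_cells`` living bacteria (all of them if fewer)
    and serialize their genomes.  An empty population yields an empty
    snapshot."""
    n = lattice.n_bacteria
    if n == 0:
        return GenomeSnapshot(iteration=lattice.iteration, sample_size=0, cells=())
    take = (
        np.arange(n)
        if n <= n_cells
        else rng.choice(n, size=n_cells, replace=False)
    )
    cells = []
    for b in take:
        genome = lattice.reg.genome(int(lattice.bact_gid[b]))
        cells.append(
            {
                "strain": lattice.strains[int(lattice.bact_strain[b])],
                "genes": [_gene_dict(g) for g in genome.loci],
                "prophages": [_prophage_dict(p) for p in genome.prophages],
            }
        )
    return GenomeSnapshot(
        iteration=lattice.iteration, sample_size=len(cells), cells=tuple(cells)
    )


def serialize(snapshot: GenomeSnapshot) -> str:
    return json.dumps(
        {
            "iteration": snapshot.iteration,
            "sample_size": snapshot.sample_size,
            "cells": list(snapshot.cells),
        },
        indent=2,
    )


def deserialize(text: str) -> GenomeSnapshot:
    raw = json.loads(text)
    return GenomeSnapshot(
        iteration=raw["iteration"],
        sample_size=raw["sample_size"],
        cells=tuple(raw["cells"]),
    )


def snapshot_genomes(snapshot: GenomeSnapshot) -> list[Genome]:
    """Rebuild the exact Genome objects recorded in a snapshot."""
    genomes = []
    for cell in snapshot.cells:
        loci = tuple(
            None
            if g is None
            else Gene(
                gene_id=g["gene_id"],
                category=g["category"],
                drug=g["drug"],
                active=g["active"],
                provenance=g["provenance"],
            )
            for g in cell["genes"]
        )
        prophages = tuple(
            Prophage(
                genotype=PhageGenotype(**p["genotype"]),
                start_locus=p["start_locus"],
                span=p["span"],
            )
            for p in cell["prophages"]
        )
        genomes.append(Genome(loci=loci, prophages=prophages))
    return genomes
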