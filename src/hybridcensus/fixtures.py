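"""Deterministic regression fixtures for the gene-tree census.

The flagship fixture is an 8063-tree forest over a Galliformes-style taxon
set in which the focal (hybrid) tip's sister categories are fixed by
quota: 5910 singleton-sister trees, 45.0% of
them with the junglefowl-lineage sire as sister, 34.0% with the
guineafowl-lineage dam, 0.2% with the cracid representative, the rest
spread over the remaining taxa, and 2153 multi-leaf-sister trees.  Running
:func:`hybridcensus.treecensus.sister_census` over the forest must
reproduce the sidecar counts exactly — quota sampling makes the category
counts a construction, not an estimate.
"""

from __future__ import annotations

import json
from pathlib import Path

from .simdata import GeneTreeForestSpec, simulate_gene_trees

FOCAL = "hybrid"
OUTGROUP = "Anas_platyrhynchos"

#: 17 Galliformes-style candidate taxa (genus_species labels)
CANDIDATE_TAXA = [
    "Gallus_gallus",
    "Numida_meleagris",
    "Penelope_pileata",
    "Meleagris_gallopavo",
    "Colinus_virginianus",
    "Phasianus_colchicus",
    "Coturnix_japonica",
    "Pavo_cristatus",
    "Chrysolophus_pictus",
    "Syrmaticus_mikado",
    "Crossoptilon_crossoptilon",
    "Tympanuchus_cupido",
    "Centrocercus_urophasianus",
    "Lagopus_muta",
    "Bonasa_umbellus",
    "Alectura_lathami",
    "Odontophorus_gujanensis",
]

N_TREES = 8063
N_SINGLETON = 5910
SIRE_SISTER_COUNT = 2660  # 2660/5910 = 45.0% Gallus_gallus
DAM_SISTER_COUNT = 2009  # 2009/5910 = 34.0% Numida_meleagris
CRACID_SISTER_COUNT = 12  # 12/5910 = 0.2% Penelope_pileata


def fixture_quota() -> dict[str, int]:
    """Exact per-category tree counts of the census fixture."""
    quota = {
        "Gallus_gallus": SIRE_SISTER_COUNT,
        "Numida_meleagris": DAM_SISTER_COUNT,
        "Penelope_pileata": CRACID_SISTER_COUNT,
    }
    rest = [
        t
        for t in CANDIDATE_TAXA
        if t not in ("Gallus_gallus", "Numida_meleagris", "Penelope_pileata")
    ]
    remaining = N_SINGLETON - sum(quota.values())
    base, extra = divmod(remaining, len(rest))
    for i, t in enumerate(rest):
        quota[t] = base + (1 if i < extra else 0)
    quota["__multi__"] = N_TREES - N_SINGLETON
    return quota


def build_census_fixture(
    seed: int = 0, outdir: str | Path | None = None
) -> tuple[list[str], dict]:
    """Build the quota-sampled 8063-tree forest and its expected-census sidecar.

    Returns (newick strings, sidecar dict).  With ``outdir`` the forest is
    written as ``fixture_forest.nwk`` plus ``fixture_forest.expected.json``.
    """
    quota = fixture_quota()
    taxa = [FOCAL, OUTGROUP] + CANDIDATE_TAXA
    singles = {sp: n for sp, n in quota.items() if sp != "__multi__"}
    mixture = {sp: n / N_TREES for sp, n in singles.items()}
    spec = GeneTreeForestSpec(
        n_trees=N_TREES,
        taxa=taxa,
        focal=FOCAL,
        outgroup=OUTGROUP,
        sister_mixture=mixture,
        non_singleton_fraction=quota["__multi__"] / N_TREES,
        quota_counts=quota,
        seed=seed,
    )
    trees = simulate_gene_trees(spec)
    sidecar = {
        "n_trees": N_TREES,
        "n_singleton": N_SINGLETON,
        "n_multi_sister": quota["__multi__"],
        "singleton_counts": singles,
        "focal": FOCAL,
        "outgroup": OUTGROUP,
        "seed": seed,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "fixture_forest.nwk", "w") as fh:
            for t in trees:
                fh.write(t + "\n")
        (outdir / "fixture_forest.expected.json").write_text(
            json.dumps(sidecar, indent=2)
        )
    return trees, sidecar
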