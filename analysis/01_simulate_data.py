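"""Generate the synthetic study inputs.

Emits, under results/synthetic_inputs/:
  specimens.csv        dissection-style specimen morphometrics (six families,
                       110 species, ln-scale noise 0.1 around the published
                       family power functions)
  museum_species.csv   IT-only museum species means (56 melittid species,
                       7 genera, rainfall-region memberships 44/13/12/20)
  genus_backbone.nwk   ultrametric pure-birth backbone over the 7 genera
  species_tree.nwk     backbone with species grafted as equal-branch polytomies
  comparative.csv      Brownian ln(IT) traits (no region effect: the null)
                       with nested taxonomy and one modeling region/species
"""

import argparse
import math
from pathlib import Path

import pandas as pd

from beeallometry import morphodata as md
from beeallometry import phylocomp as pc
from beeallometry import synthdata as sd


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", default="results/synthetic_inputs")
    args = ap.parse_args()
    outdir = Path(args.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # specimen-level morphometrics at the study conditions
    records = sd.gen_specimens(sd.SynthConfig(seed=args.seed))
    specimens = pd.DataFrame(
        [
            {
                "specimen_id": r.specimen_id, "species": r.species,
                "genus": r.genus, "family": r.family, "sex": r.sex,
                "it_mm": r.it_mm, "glossa_mm": r.glossa_mm,
                "prementum_mm": r.prementum_mm,
            }
            for r in records
        ]
    )
    specimens.to_csv(outdir / "specimens.csv", index=False)
    n_species = specimens["species"].nunique()
    print(f"specimens.csv: {len(specimens)} specimens, {n_species} species, "
          f"{specimens['family'].nunique()} families")

    # museum-style species table with the fixed region membership pattern
    table = sd.gen_museum_species_table(seed=args.seed + 1)
    md.means_to_frame(table).to_csv(outdir / "museum_species.csv", index=False)
    counts = {r: sum(r in m.regions for m in table) for r in md.REGIONS}
    print(f"museum_species.csv: {len(table)} species; region counts {counts}")

    # genus backbone and grafted species tree
    backbone = sd.gen_tree(len(sd.GENERA_TAXONOMY), birth_rate=1.0,
                           seed=args.seed + 2)
    for leaf, genus in zip(backbone.leaf_node_iter(), sd.GENERA_TAXONOMY):
        leaf.taxon.label = genus
    pc.write_newick(backbone, outdir / "genus_backbone.nwk")
    mapping = {}
    for m in table:
        mapping.setdefault(m.genus, []).append(m.species)
    species_tree = pc.graft_species_polytomies(backbone, mapping)
    pc.write_newick(species_tree, outdir / "species_tree.nwk")
    depths = list(pc.tip_depths(species_tree).values())
    print(f"species_tree.nwk: {len(depths)} tips, ultrametricity deviation "
          f"{max(depths) - min(depths):.2e}")

    # comparative dataset: Brownian ln(IT) under the null (no region effect)
    assignment = {
        m.species: pc.majority_region({r: 1 for r in m.regions}) for m in table
    }
    traits = sd.gen_brownian_traits(
        species_tree, sigma2=0.05, root_state=math.log(2.58),
        region_effects=None, region_assignment=assignment, seed=args.seed + 3,
    )
    taxonomy = pd.DataFrame(
        {
            "species": [m.species for m in table],
            "genus": [m.genus for m in table],
            "tribe": [sd.GENERA_TAXONOMY[m.genus][0] for m in table],
            "subfamily": [sd.GENERA_TAXONOMY[m.genus][1] for m in table],
        }
    )
    comparative = traits.merge(taxonomy, on="species")
    comparative.to_csv(outdir / "comparative.csv", index=False)
    print(f"comparative.csv: {len(comparative)} species, regions "
          f"{sorted(comparative['region'].unique())}")


if __name__ == "__main__":
    main()
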