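"""Simulate the study-sized variant panel and write its allele tables.

Generates 9 benign controls, 14 pathogenic controls and 54 query variants,
simulates the day-2 baseline plus the four day-12 arms (untreated, PARPi,
cisplatin, MMC) at 3 replicates x 10,000 reads/sample, and writes one
allele table per sample plus the edit definitions and the annotation table
under results/01_simulated/.
"""

import argparse
from pathlib import Path

from crisprselect import acmg, ingest, synthetic

OUT = Path(__file__).resolve().parent.parent / "results" / "01_simulated"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=20)
    args = parser.parse_args()

    panel = synthetic.generate_variant_panel(9, 14, 54, seed=args.seed)
    cfg = synthetic.SimulationConfig(seed=args.seed, n_reads_per_sample=10_000, n_replicates=3)
    edit_defs = {
        pv.variant_id: synthetic.make_edit_definition(pv.variant_id, args.seed) for pv in panel
    }
    samples = [sc for pv in panel for sc in synthetic.simulate_counts(pv.profile, cfg)]
    manifest = synthetic.write_allele_tables(samples, edit_defs, OUT)
    ingest.write_edit_definitions(edit_defs.values(), OUT / "edit_definitions.tsv")
    acmg.write_annotation_table((pv.annotation for pv in panel), OUT / "annotations.tsv")

    roles = [pv.annotation.role for pv in panel]
    print(f"panel: {len(panel)} variants "
          f"({roles.count('control_benign')} benign controls, "
          f"{roles.count('control_pathogenic')} pathogenic controls, "
          f"{roles.count('query')} queries)")
    print(f"wrote {len(manifest)} allele tables to {OUT}")


if __name__ == "__main__":
    main()
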