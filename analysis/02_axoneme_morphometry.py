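#!/usr/bin/env python
"""Axoneme morphometry of the simulated mouse and human cilia: per-tubule
lengths and tortuosity, doublet pairing, B-before-A termination order, and
class-level summaries.

Reads the skeletons written by 01_simulate_scenes.py and writes tidy
measurement tables under results/.
"""

from pathlib import Path

from ciliamorph import io, morphometry

OUT = Path(__file__).resolve().parents[1] / "results"


def analyze(name: str) -> None:
    skeletons = io.read_skeletons(OUT / f"{name}_skeletons.swc")
    # doublet pairing concerns axonemal A/B tubules; basal-body triplet
    # stubs sit just as close to the B-tubules and are not pairing candidates
    doublet_tubules = [p for p in skeletons if p.tubule_class in ("A", "B")]
    pairs = morphometry.pair_doublets(doublet_tubules)
    for poly in skeletons:
        poly.pair_id = pairs.get(poly.source_id)
    table = morphometry.measure_tubules(skeletons)
    io.write_measurements(table, OUT / f"{name}_morphometry.csv")

    frac_b_first, pair_table = morphometry.termination_stats(skeletons)
    io.write_measurements(pair_table, OUT / f"{name}_termination.csv")

    print(f"--- {name} axoneme ---")
    for s in morphometry.summarize_lengths(table[table.tubule_class.isin(["A", "B"])]):
        print(f"  {s.label}-tubules: {s.mean/1000:.2f} +/- {s.sd/1000:.2f} um (n={s.n})")
    tort = table.loc[table.tubule_class.isin(["A", "B"]), "tortuosity_ratio"]
    print(f"  tortuosity {tort.mean():.4f} (range {tort.min():.4f}-{tort.max():.4f})")
    print(f"  doublets paired: {len(pair_table)}; "
          f"B terminates first in {100 * frac_b_first:.0f}% of pairs; "
          f"inverted pairs: {int(pair_table.inverted.sum())}")


def main() -> None:
    for name in ("mouse", "human"):
        analyze(name)


if __name__ == "__main__":
    main()
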