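# paralogsites

Clade-aware alignment decomposition and relaxed symplesiomorphy /
synapomorphy character-site detection for deeply divergent protein
paralog pairs — with a scenario simulator for telling genuine deep
divergence apart from long-branch attraction (LBA).

## The problem

Some aminoacyl-tRNA synthetase families (SerRS, ThrRS) contain, besides
the *common* form found across the three domains of life, a *rare* form
restricted to subsets of Archaea that branches anomalously deeply — at
or below the split between the paralog families. Deep placements of
fast-evolving lineages are exactly what LBA fabricates, so tree support
alone cannot establish that the rare forms are genuinely ancient. This
package implements two tree-free analyses for such paralog pairs:

1. **Alignment decomposition.** Columns that align reliably *between*
   two distant families are few; many more align well only *within* one
   family. Decomposition concatenates the mutually exclusive sets of
   globally well-aligned and clade-specific well-aligned columns into
   one composite alignment, preserving within-clade signal without
   trusting cross-family homology at clade-specific columns. With mask
   sizes |S| = 107 (shared), |C₁| = 129, |C₂| = 217, the composite has
   453 columns, 107+129 = 236 informative for family 1's internal split
   and 107+217 = 324 for family 2's.

2. **Relaxed character sites.** For an ingroup form I, sister form Sis
   (same family) and outgroup O (the other family), a column is a
   *symplesiomorphy* for I if some residue class C has
   share_I(C) > 50% and share_O(C) > 50% while **no** sister taxon
   carries C — a shared ancestral state recording one substitution on
   the sister stem; it is a *synapomorphy* if share_I(C) > 50% and C is
   absent from sister and outgroup alike. If the rare form were an LBA
   artifact nested inside the common form, rare-form symplesiomorphies
   with the opposing family could arise only by convergence and should
   be very rare; under genuine deep divergence their count should be
   comparable to the common form's and scale with the sister stem
   length. The package's simulator turns that qualitative argument into
   a measured, testable contrast.

## Worked example

```python
import paralogsites as ps

# benchmark alignment: 4 groups x 100 taxa; seven designated columns
# reproduce published per-group conservation profiles of SerRS/ThrRS
# character sites, the rest are engineered non-calls
fx = ps.make_benchmark_fixture()
calls = ps.scan_charsites(fx.alignment, fx.grouping)
print(ps.summarize_calls(calls).to_dict())
```

prints

```
{'symplesiomorphies': {'SerRS:rare': 3, 'SerRS:common': 4},
 'synapomorphies': {'SerRS:common': 2, 'SerRS:rare': 3},
 'weak_symplesiomorphies': {},
 'mean_conservation_percent': {'SerRS': 92.0}}
```

Three rare-SerRS symplesiomorphies against four for common SerRS —
comparable counts, the signature of genuine deep ancestry rather than
LBA (an artifactual rare clade would show ≈0) — with the defining class
conserved at 92% on average within the calling SerRS form, well above
the 50% cutoff. The synapomorphy entries are the mirror image of the
same columns seen from the other form's side.

The simulator makes the contrast explicit:

```python
from dataclasses import replace
cfg = ps.ScenarioConfig(n_columns=150, slow_site_fraction=0.5,
                        slow_rate_multiplier=0.15,
                        within_group_length=0.1, seed=11)
deep = ps.scenario_experiment(cfg, 100)
lba = ps.scenario_experiment(replace(cfg, preset="lba"), 100)
print(deep.mean_symplesiomorphies[("A", "rare")],   # 9.59
      lba.mean_symplesiomorphies[("A", "rare")])    # 2.49
```

Everything is also scriptable from the shell via the `paralogsites` CLI
(`mask`, `decompose`, `charsites`, `simulate`, `fixture`, `run`).

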