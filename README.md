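# morphassign

Rebuilding a molecular-replacement model against an electron-density map:
real-space **morphing**, density-based **trimming**, and combinatorial
**sequence assignment** of the surviving segments, iterated with
density-guided loop building.

## The problem

After molecular replacement, the placed template is often locally similar
to the true structure but drifts globally (main-chain r.m.s.d. of 2 Å or
more), carries the wrong sequence, and differs by insertions and
deletions. This package takes the placed model, a density map and the
target sequence, and produces a model whose main-chain follows the map and
whose residues are assigned to the target sequence, in three stages:

1. **Morph** — for every residue, the model density of the atoms within
   6 Å of its Cα is rigidly translated (up to 2 Å, discrete search with
   half-step polish) to maximise the local Pearson correlation with the
   map; the per-residue shift vectors are boxcar-smoothed over a
   10-residue window (never across chain breaks) and applied, preserving
   intra-residue geometry exactly; connecting-peptide geometry is restored
   by restrained real-space regularisation. Six cycles by default.
2. **Trim** — residue *i* is removed when its mean atom-position density
   ρ<sub>mean</sub> < 0.5 ρ<sub>mean_all</sub> + 0.2 SD<sub>mean_all</sub>
   (statistics over all residues of the untrimmed model), or when its
   local map–model correlation in a 2.5 Å sphere is below 0.4.
3. **Assign** — each maximal contiguous segment gets a sequence offset by
   maximising an additive score: ln *p* (the estimated probability the
   placement is correct, from side-chain density), a connection term that
   *rejects* any pair of sequence-adjacent segments whose end-to-end
   distance exceeds (gap + 1) × 3.8 Å, a +10 bonus when a validated loop
   of exactly the assigned gap length connects two segments, and a
   BLOSUM62 Z-score (floored at zero) against the template sequence —
   subject to non-overlap (up to the NCS copy number) and, optionally,
   template segment order. Loops are then built between close segment
   ends through *unexplained* density (map minus model), consistent loops
   are merged in, and the assignment is repeated (three iterations by
   default).

A synthetic-case generator (`morphassign.synthetic`) produces ground-truth
structures with ideal backbone geometry, blurred noisy maps, and
deformed/mutated/indel-edited templates, so the entire pipeline is
testable without crystallographic data.

## Worked example

```python
from morphassign.synthetic import make_case, evaluate_assignment, main_chain_rmsd
from morphassign.morph import morph, MorphConfig
from morphassign.trim import trim_model
from morphassign.assign import ScoreConfig
from morphassign.loops import iterate_assignment

case = make_case(n_res=100, seed=1)     # 2 A deformation, ~60% identity,
                                        # one 4-residue deletion, 10% noise
print(f"template main-chain RMSD to truth: {main_chain_rmsd(case.template, case.truth):.2f} A")
morphed, diag = morph(case.template, case.dmap, MorphConfig())
print(f"after 6 morph cycles:              {main_chain_rmsd(morphed, case.truth):.2f} A "
      f"(mean CC {diag[-1]['mean_cc']:.3f})")
trimmed, report = trim_model(morphed, case.dmap)
print(f"trim: kept {report.n_kept}, removed {report.n_removed} "
      f"(threshold {report.threshold:.3f})")
final, history = iterate_assignment(trimmed, case.dmap, case.target_sequence,
                                    ScoreConfig(), n_iter=3, seed=1)
ev = evaluate_assignment(final, case.truth)
print(f"correctly assigned: {ev['n_correct']}/{ev['n_built']} built residues")
```

prints

```
template main-chain RMSD to truth: 2.03 A
after 6 morph cycles:              0.14 A (mean CC 0.939)
trim: kept 94, removed 2 (threshold 0.453)
correctly assigned: 100/100 built residues
```

The morphing pulled the 2 Å-deformed template onto the map (0.14 Å
residual), trimming discarded the two residues left stranded around the
template's deletion, and three assignment iterations placed all four
segments at their true offsets and rebuilt the deleted loop from the map,
yielding a complete, fully correctly assigned chain.

The same stages are available from the shell:

```sh
morphassign synth --n-res 100 --seed 1 --out-dir case
morphassign pipeline --model case/template.pdb --map case/map.mrc \
    --seq case/target.fasta --out-dir out --seed 1
```

which writes `morphed.pdb`, `trimmed.pdb`, `assigned.pdb`, a per-residue
trim report and the assignment table.

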