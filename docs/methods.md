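# Methods

## Problem and scope

Type I collagen — a heterotrimer of two α1 and one α2 chain wound into a
~300 nm triple helix — accumulates advanced glycation end-product (AGE)
cross-links with age. The two lysine–arginine AGEs handled here, glucosepane
and DOGDIC (3-deoxyglucosone-derived imidazolium cross-link), both form from
d-glucose via the Schiff base and bridge a Lys and an Arg side chain across
two chains of the same molecule. `colxscan` implements the analysis pipeline
around that chemistry: geometric candidate search, cross-link/reference
bookkeeping, windowed formation-enthalpy estimation from energy time series,
D-band gap/overlap classification, and interaction-domain annotation. It
does **not** run molecular dynamics; a synthetic structure and energy-trace
generator stands in for the MD engine so every stage is testable end to end.

## Dual residue numbering

Sites are labelled in two frames: full-sequence (UniProt) position and
triple-helical position. Brute force over all 24 dual-numbered residue pairs
in the packaged candidate table yields a single consistent offset per chain
kind — α1: uniprot − helical = 167, α2: 96 — stored as constants and
re-derived in the test suite. The helical domain is taken as 1014 residues
for both chain kinds.

## Candidate search

A cross-chain Lys/Arg pair is a candidate if any of three distances is
within the cut-off (default 5 Å, twice the shortest N–N separation inside
the DOGDIC core): Nζ–Nη, Cε–Nε, Cδ–Cδ. The η designation is unbranched in
the criterion, so Nζ–Nη is resolved permissively as min(NH1, NH2).
Hydroxylysine is not a donor. Scanning a single conformer is the default;
minimum-image distances are opt-in (intra-molecular sites are the object of
study). The scanner is vectorised; its correctness oracle in the tests and
acceptance script is an independent plain-python all-pairs loop, compared
exactly on 100 random synthetic structures at 4/5/6 Å.

## Synthetic structures

`build_triple_helix` winds Gly-X-Y chains as an idealized straight-axis
helix: 2.86 Å rise per residue, 3.33 residues/turn per chain (left-handed),
2.8 Å chain radius, 120° between chains, one residue of axial stagger. This
is a deliberate simplification of the crystal-derived conformation — no
supercoil writhe, schematic backbone geometry — sufficient for exercising a
distance-criterion scanner, and nothing more. Side chains sit on fixed
extended rotamers pointing radially outward; `plant_site` first rigid-rotates
the lysine side chain about Cα–Cβ towards a target criterion distance and
falls back to rigid translation of the side chain beyond Cβ, achieving the
target to ≪0.01 Å while leaving every other atom bit-identical. Because the
tails of staggered chains extend the molecule by `2 × stagger` residues,
the "extent ≈ N × rise" property is asserted at N ≥ ~100 residues where the
2% band absorbs the tails.

## Synthetic energy traces

`gen_energy_trace` emulates a production-run total-energy series: a linear
drift decaying from `drift_amplitude` to zero at `equil_time`, plus
stationary AR(1) noise (innovation SD `noise_sd`, lag-1 coefficient
`ar1_phi`) about `mean_energy`. Defaults are the study conditions the
pipeline is meant for: 60 ns at 1 ps sampling, equilibration ending at
35 ns, φ = 0.8 (integrated autocorrelation time ≈ 9 ps), innovation SD
16 kcal/mol (stationary SD ≈ 26.7), mean −120,000 kcal/mol, drift amplitude
400 kcal/mol. With these values the block SEM of a 25 ns-window energy
difference lands near 0.7 kcal/mol, the statistical error scale reported
for the simulations this emulates. What the generator does **not** emulate:
non-Gaussian tails, slow conformational transitions, correlated
xlink/reference noise, or any coupling between structure and energetics —
passing tests show the estimator is correct for well-behaved stationary
series, not that real trajectories are converged.

## Formation enthalpy and its error

ΔH = mean(cross-linked total energy) − mean(reference total energy) over the
analysis window; favourable means strictly ΔH < 0. The default window policy
is the final 25 ns of a 60 ns trace (`fixed_last`), reflecting convergence
at 35 ns; an `auto` policy is provided as a documented heuristic (earliest
time from which the reverse cumulative mean stays within 0.1 × tail SD of
the final-10 ns mean) and detects the synthetic generator's 35 ns elbow at
≈31 ns. SEM uses block averaging (default 5 contiguous blocks of the
difference series; per-frame SEM available, and demonstrably smaller under
autocorrelation). ΔH is exactly independent of the block count; only the
SEM estimate varies.

A note on coverage: a "planted offset within 2 × estimated SEM" check has
nominal coverage P(|t_{k−1}| ≤ 2) with k blocks — 88.4% at k = 5, rising
towards the Gaussian 95.45% only for large k. The recovery study therefore
uses k = 100 (250 ps blocks ≫ the 9 ps correlation time). Simulation puts
the true coverage of that check under the default trace conditions at
≈95.0% — residual autocorrelation biases the blocked SEM slightly low — so
a ≥95% pass threshold on 200 repeats sits at the edge of what the check can
honestly deliver; observed values at fixed seeds range 93.5–94.5%.

## Cross-link templates and mass balance

Templates carry idealized 3-D coordinates with the lysine-derived nitrogen
N1 and the two arginine-derived bridging nitrogens N2/N3 placed so the
N1–N2/N1–N3 separations realize the kind's fingerprint exactly: 2.5/3.5 Å
(DOGDIC), 2.6/3.8 Å (glucosepane); DOGDIC is annotated with three chain
hydroxyls, glucosepane two. Inserting a cross-link removes both side chains
beyond Cβ (combined C6H18N4 at pH 7) and grafts the template (C12H24N4O3 =
those heavy atoms + glucose − 3 H2O); the reference system instead keeps
the native protein plus one open-chain glucose and gives up three waters.
Element balance between the two systems is exact by construction and
re-verified from molecular formulas on every feasible synthetic site. The
per-kind hydrogen adjustment (+6 H on the protein) is a documented constant;
the schematic connectivity does not fix it atom by atom. Geometric
feasibility uses the doubling rule: min criterion distance ≤ 2 × nn_short.

## D-band mapping and registration

With D = 67 nm and a 2.86 Å rise, one D-period is 234 residues (neither
number is part of the site table itself; both are standard fibrillar
values). A helical position maps to an axial fraction
`((pos − 1 + offset) mod 234) / 234`; the frame is anchored at a gap start,
so fractions below 0.54 are gap and the rest overlap. This anchoring makes
the integer overlap window 107 residues wide (the overlap-anchored
alternative gives 108, since 234 is not divisible by 50), and an exhaustive
check over all 234 offsets shows 107 is the *only* window width under which
exactly one of the six favourable sites can fall in the overlap region —
with 108 the minimum is two. The packaged registration offset (179) is the
unique offset realizing the one-overlap/five-gap split, with the site at
helical ~915–918 as the overlap exception; each site is represented by the
smaller helical position of its residue pair. The registration is a derived
calibration against that qualitative split — the underlying fibril
registration is graphical in the source material, never numeric — and is
exposed as a plain parameter everywhere.

## Composition accounting

`compute_composition` does formal pH-7 accounting: Lys/Hyl/Arg +1, Asp/Glu
−1, His neutral, termini zwitterionic and cancelling per chain;
hydroxylation (Hyp/Hyl) adds one oxygen (15.9994 g/mol) and no charge.
Masses come from Biopython's average residue weights (one water per chain
for the termini); the water mass constant is 18.0153 g/mol so hydration
ratios are stable at two decimals. Reproducing the full molecule's +33 net
charge and 0.75 g/g hydration requires the real mature-chain sequences,
which are not packaged; the corresponding check fails with an explicit
message until a sequence FASTA is supplied.

## Problem sizes

Defaults used by the test suite and acceptance script: 100 random synthetic
structures (≤ ~120 residues over three chains) for scanner-oracle
equivalence; 200 seeded trace pairs of 60,000 samples each for the recovery
study; 50 realizations per series length for the SEM scaling law
(10³–10⁵ samples). These sizes were chosen so the whole analysis reruns in
seconds while keeping every statistical check adequately powered.

## Known limitations

* No force-field energetics anywhere; the enthalpy module analyses energy
  tables, it does not produce them.
* The idealized helix is not the crystal-derived conformation; planted-site
  scans validate the scanner, not collagen geometry.
* The domain annotation is a qualitative site → biomolecule-name lookup,
  not an interval map.
* The D-band registration is calibrated, not measured; alternative
  registrations are one parameter away.
* mmCIF, AMBER topologies, pKa prediction and trajectory formats beyond
  multi-frame PDB/TSV are out of scope.
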