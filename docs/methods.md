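# Methods

## Problem and model

Channel-activating proteases open the epithelial sodium channel (ENaC) by
cleaving the γ-subunit twice — once proximally, in the furin region around
R138 (135-RKRR-138), and once distally — thereby excising an inhibitory
tract of roughly 40 residues whose central 11-mer (γ-11,
153-RFSHRIPLLIF-163) is the key inhibitory element. The package predicts
the distal cleavage position of a trypsin-like protease (the reference case
is the TMPRSS2 catalytic domain, triad H296/D345/S441, S1-pocket aspartate
D435) from docked ensembles of 6-mer substrate peptides, using geometry
alone: no energetic rescoring, hydrogen-bond networks or solvent terms.

A binding mode counts as productive when

1. the charged side-chain group of a basic residue (Arg NH1/NH2/NE or Lys
   NZ) lies within 4 Å of the S1 aspartate carboxylate (minimum heavy-atom
   distance over the OD1/OD2 pair), the standard geometric proxy for a
   salt bridge, and
2. that residue's backbone carbonyl carbon lies within 4 Å of the catalytic
   serine's OG oxygen, as required for nucleophilic attack on the scissile
   bond.

The salt-bridge operationalisation (charged-group *minimum* distance,
hydrogens excluded) and the strictness of the inequalities are configurable
decisions: the qualitative description behind them ("distance to the side
chain of the aspartate … less than 4 Å") does not pin down atoms or
boundary behaviour, so the defaults are the field-standard salt-bridge
criterion and strict `<`, with `strict_inequality=False` available for
sensitivity analysis. Criterion 2 is evaluated only for the S1 occupant —
the scissile bond is defined by the residue actually in the pocket — and a
mode whose basic residue passes (2) but fails (1) is never selected.
Occupant ties are resolved by smallest salt-bridge distance, then Arg
before Lys, then lower residue number.

## Specificity rules and candidate enumeration

The P1/P2 rule set encodes trypsin-like specificity as reported for
TMPRSS2: P1 ∈ {R, K} with Arg preferred, Lys at P2 incompatible with
cleavage. The P2 veto *flags* candidates rather than removing them, so
reports show every basic residue in a region; the Arg-over-Lys preference
is used only for tie-breaking in occupant calls and site ranking, never to
exclude Lys sites. Docking windows follow the P4–P2′ convention (6 residues
for a full context — the typical length of a protease recognition motif);
windows truncated at sequence termini are emitted with a warning rather
than an error, since the analysis itself never docks truncated windows but
downstream code needs defined behaviour.

The distal-region test sequence is assembled strictly from published
segments (K168, 169-GKARDF-174, 175-FTGR-178, 177-GRKRKV-182,
187-IHKASN-192, plus 135-RKRR-138 and γ-11 for the full 134–192 span);
unpublished residues (183–186 and gaps before 168) are carried as the
placeholder `X`, which is never a P1 candidate, never triggers the P2 veto,
and propagates NaN masses. Mutant construct names (`RKRK178AAAA;K168A;…`)
are parsed with a dual-anchoring rule: published names anchor a
multi-residue run's printed number inconsistently (at the run's first
residue for 178-RKRK-181, at its last for 135-RKRR-138), so the parser
tries both anchorings against the wild-type sequence and errors if neither
or both match.

## Ensemble statistics

Pairwise RMSD is computed over backbone heavy atoms (N, CA, C, O; an
all-heavy-atom scope is available) **without superposition**, in the shared
receptor frame: the quantity of interest is placement in the catalytic
site, which superposition would erase. The backbone default reflects that
the clustering claim concerns the peptide's backbone conformation. Within
each ensemble, all-vs-all pairwise RMSDs are collected separately for
selected and discarded modes ("corresponding binding modes" is read as
all-vs-all within group; a reference-pose pairing would be the
alternative). The two samples are compared with a two-sided Mann–Whitney U
test by default; because pairwise distances from the same poses are not
independent, a label-permutation test (difference of within-group mean
RMSD, 1000 permutations, seeded) is offered and the report always names the
method. Pass fractions are reported to one decimal in percent, distances to
two decimals; JSON output carries unrounded numbers.

Sites are ranked by selected-mode S1-occupancy count across all ensembles
(descending), ties broken by P1 preference then position.

## Fragment mapping

Fragment masses are unmodified average masses (Biopython's average residue
weights; each hydrolysis adds one water, 18.015 Da). Real γ-ENaC fragments
are glycosylated, so apparent gel mobilities will differ — predicting
apparent kDa is deliberately out of scope. The inhibitory tract is defined
as `(proximal P1, distal P1]` (139–178 by default, configurable). The
release call is three-valued: *released* when cuts bracket the tract;
*released with a truncation note* when the proximal cut falls inside the
tract but removes at most the first residue of γ-11 (the partial-activation
case of cleavage after R153); *retained-partial* when a cut lands deeper
inside the key span; *retained* otherwise (one cut can never excise an
internal tract).

## Synthetic data generator

`make_mock_receptor` builds a four-residue receptor containing exactly the
anchors the criteria touch, with the serine OG 7 Å from the S1 carboxylate
(catalytic-site scale). `make_ensemble` emulates the two observed mode
classes:

* **Productive poses** start from an idealised extended peptide (3.8 Å CA
  spacing; backbone + CB everywhere, full charged groups only for Arg/Lys —
  the only atoms the criteria read). A two-point rigid fit places the
  occupant's reference charged atom exactly `salt_bridge_target` (default
  3.0 Å) from OD1 and its carbonyl carbon exactly `scissile_target`
  (default 3.4 Å) from OG; the free spin about the two-point axis is chosen
  to maximise the clearance of *other* basic residues from the carboxylate,
  so the intended occupant is unambiguous. Each pose is then a small random
  rigid perturbation (per-axis translation SD `jitter_sd`, default 0.3 Å;
  rotation SD `jitter_sd`/10 rad, i.e. tied to a 10 Å lever arm — rigid
  transforms keep poses valid conformers, unlike per-atom noise),
  resampled until the pose still passes both criteria with the intended
  occupant nearest the pocket.
* **Decoys** are uniform random rigid placements in a cube of edge
  `decoy_box` (default 40 Å, the docking-grid long edge) centred on the
  catalytic site, resampled until every basic residue clears *both*
  thresholds by at least `margin` (default 1 Å).

Rejection sampling caps at 10 000 attempts per pose and then errors, so
infeasible configurations fail loudly. All distance checks inside the
generator are computed directly with numpy, independent of the criteria
engine, so ground-truth labels do not presuppose the code they are used to
test. The number of productive poses is `round(fraction × n_poses)`;
defaults (90 poses per ensemble, 10 runs × 9 modes) match the documented
docking campaign, as do the default productive fractions used in the demo
and acceptance campaign (≈0.45 / 0.35 / 0.08 for the three wild-type
windows, 0.45 / 0.08 for the GAARDF / GKAADF mutants — the documented
pass-fraction regime).

What the generator does **not** emulate: docking-engine score
distributions, physically realistic side-chain rotamers or backbone
torsions, receptor flexibility, or partial-pass poses near the thresholds.
Passing tests therefore demonstrate that the pipeline's logic and
statistics are correct under the assumed two-class geometry, not that a
real docking campaign would reproduce the published pass fractions — that
requires an externally built receptor model and a docking engine, which the
adapter supports (`DockingCampaign.engine_path`) but nothing in the test
surface needs.

## Numerical and design choices

* Poses are assumed to share the receptor coordinate frame (docking-output
  convention); no superposition is performed anywhere.
* Hydrogens are dropped at ingest; alternate locations beyond the first are
  ignored; insertion codes are rejected (author numbering must be plain
  integers). PDB round-trips are exact to the format's 10⁻³ Å precision.
* The docking grid centre defaults to the triad-CA centroid ("close to the
  catalytic triad" is not a coordinate); reproduction runs against a real
  receptor should report sensitivity to ±2 Å centre shifts.
* The receptor is treated as rigid throughout.
* The adapter's PDBQT reader covers the subset AutoDock Vina emits (MODEL
  blocks, ATOM/HETATM with AutoDock atom types, VINA RESULT remarks);
  pose ids are (run, mode)-lexicographic regardless of filesystem order,
  and a short run warns instead of failing.
* Problem sizes in the test and acceptance surface (90-pose ensembles, 20
  recovery seeds, 1000 permutations) were chosen to exercise the documented
  campaign geometry at desk scale; the whole suite runs in seconds.

## Known limitations

* The geometric filter is binary; near-threshold modes carry no partial
  credit, and no energetics are considered.
* Site ranking aggregates occupancy counts across windows of potentially
  overlapping sequence; a residue docked in two windows is counted per
  window.
* Fragment masses ignore all post-translational modification, and spans
  containing unpublished (`X`) residues yield NaN masses by design.
* The Mann–Whitney p-value on pairwise RMSD lists overstates independence;
  the permutation test is the conservative alternative and both are
  reported with their method label.
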