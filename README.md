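# cleavedock

Docking-based prediction of trypsin-like protease cleavage sites in a
substrate, built around the case of TMPRSS2 cleaving the γ-subunit of the
epithelial sodium channel (ENaC). The package is for structural
bioinformaticians and channel physiologists who have (or simulate) ensembles
of docked substrate-peptide binding modes and want a reproducible,
geometry-based call on *where* a protease cleaves.

## The method

Proteolytic activation of ENaC requires two cuts in the γ-subunit: a
proximal (furin-region) cut and a distal cut, which together excise an
inhibitory tract of ~40 residues. To predict where a trypsin-like protease
such as TMPRSS2 makes the distal cut, the analysis proceeds in four stages:

1. **Candidate enumeration.** Every Arg/Lys in the region of interest is a
   candidate P1 site (Schechter–Berger nomenclature: P1 is N-terminal to the
   scissile bond, protease subsite S1 binds the P1 side chain). TMPRSS2
   prefers Arg over Lys at P1, and a Lys at P2 vetoes cleavage — vetoed
   sites are flagged, not dropped. Candidates map to 6-mer (P4–P2′) docking
   windows.
2. **Geometric pose filtering.** Each docked binding mode of a window
   peptide is kept as *productive* only if two criteria hold:
   - d(P1 charged group, S1 Asp carboxylate) < 4 Å — minimum heavy-atom
     distance between Arg NH1/NH2/NE (or Lys NZ) and Asp OD1/OD2, a
     salt-bridge-compatible contact at the bottom of the S1 pocket;
   - d(P1 carbonyl C, catalytic Ser OG) < 4 Å — the scissile carbonyl must
     sit within striking distance of the catalytic serine's hydroxyl
     oxygen.
   With several basic residues in the pocket, the S1 occupant is the one
   with the smallest salt-bridge distance (ties: Arg before Lys, then lower
   position).
3. **Ensemble statistics.** Per window: the pass fraction (% of modes
   selected out of, by default, 90 = 10 runs × 9 modes), S1 occupancy counts
   per P1 position, and the contrast in pairwise backbone RMSD (computed in
   the shared receptor frame, no superposition) between selected and
   discarded modes, tested with a two-sided Mann–Whitney U (or a seeded
   label-permutation test). Sites are ranked by selected-mode occupancy.
4. **Fragment mapping.** A proximal+distal cleavage pair is translated into
   N-terminal / released-tract / C-terminal fragments with lengths and
   unmodified average masses, plus a released / retained-partial / retained
   call for the inhibitory tract against the key inhibitory 11-mer
   (153-RFSHRIPLLIF-163).

A synthetic-data module generates mock receptors and labelled pose
ensembles with the same two-class structure (tight productive cluster +
diffuse decoys), so the entire pipeline is testable with no docking engine
or downloads; an adapter ingests real AutoDock-Vina-style output (multi-model
PDB or PDBQT) when available.

## Worked example

```python
import cleavedock as cd

receptor = cd.make_mock_receptor()
pose_sets = {}
for window, start, occupant, fraction, seed in [
    ("GKARDF", 169, 172, 0.45, 101),
    ("GRKRKV", 177, 178, 0.35, 102),
    ("IHKASN", 187, 189, 0.08, 103),
]:
    config = cd.SyntheticEnsembleConfig(
        peptide_window=window, peptide_start=start, occupant_position=occupant,
        n_poses=90, productive_fraction=fraction, seed=seed)
    pose_sets[window], _ = cd.make_ensemble(config, receptor)

results = cd.CleavageSiteModel(receptor, pose_sets).fit()
print(results.summary())
```

prints

```
Cleavage-site docking analysis
==============================================================
Selection criteria: salt bridge < 4.0 A (P1 side chain to S1 Asp OD1/OD2),
                    scissile C to Ser OG < 4.0 A

GKARDF: 40/90 binding modes selected (44.4%)
    S1 occupant R172: 40 modes
    pairwise backbone RMSD: selected 0.80 A vs discarded 29.16 A (Mann-Whitney U (two-sided), p = 0)
GRKRKV: 31/90 binding modes selected (34.4%)
    S1 occupant R178: 31 modes
    pairwise backbone RMSD: selected 0.72 A vs discarded 27.68 A (Mann-Whitney U (two-sided), p = 2.01e-240)
IHKASN: 7/90 binding modes selected (7.8%)
    S1 occupant K189: 7 modes
    pairwise backbone RMSD: selected 0.73 A vs discarded 29.31 A (Mann-Whitney U (two-sided), p = 2.54e-15)

Predicted cleavage sites (by selected-mode occupancy):
   1. R172 (40 modes, 44.4% of GKARDF)
   2. R178 (31 modes, 34.4% of GRKRKV)
   3. K189 (7 modes, 7.8% of IHKASN)
```

Each window line gives the pass fraction — the share of the 90 docked
binding modes compatible with proteolysis — and which residue's side chain
occupied the S1 pocket in the selected modes. The RMSD line shows that
selected modes form a tight structural cluster (sub-Å spread) while
discarded modes scatter across the docking box; the final ranking reads as
"R172 and R178 are the strongest predicted cleavage sites, K189 a weak one".

The same pipeline is scriptable from the shell (`cleavedock simulate /
enumerate / evaluate / summarize / fragments / run`); every subcommand
writes a `provenance.json` with its configuration and input checksums.

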