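"""Degenerate-codon library design statistics.

Computes the size of a three-site combinatorial library from its allowed
residue sets, expands the NNK codon, and evaluates how many colonies must
be screened to cover a site-saturation library.
"""

from hamascreen import (
    NNK,
    LibraryDesign,
    LibrarySite,
    complete_coverage_probability,
    count_point_mutants,
    coverage,
    library_size,
    mix_ratios,
)

design = LibraryDesign(
    sites=(
        LibrarySite(660, tuple("AFGLV")),
        LibrarySite(702, tuple("FHSTWY")),
        LibrarySite(752, tuple("CALMSTV")),
    )
)
print(f"triple-mutant library size: {library_size(design)} variants "
      f"(5 x 6 x 7)")
print(f"site saturation of 15 positions: {count_point_mutants(15)} "
      f"point mutants\n")

print(f"NNK expands to {NNK.n_codons} codons encoding "
      f"{len(NNK.amino_acids)} amino acids and {NNK.n_stop_codons} stop")
print(f"codons per residue (subset): "
      f"L={NNK.aa_counts['L']}, A={NNK.aa_counts['A']}, W={NNK.aa_counts['W']}")

print(f"\noligo mixing for a 2-codon + 4-codon pair: "
      f"{[(o, round(f, 3)) for o, f in mix_ratios([('o1', 2), ('o2', 4)])]}")

for n in (46, 92, 184):
    exp = coverage(n, NNK)
    full = complete_coverage_probability(n, NNK)
    print(f"\n{n:>4} colonies: expected coverage {exp:.1%}, "
          f"P(all 20 residues seen) {full:.1%}")

print("""
'Expected coverage' is the mean fraction of the 20 amino acids observed;
at 92 colonies it stays above the 90% screening heuristic.  Seeing every
residue at least once is a stricter requirement and needs more colonies.""")
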