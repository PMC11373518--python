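"""Match putatively orthologous TEs between two IGSs.

Builds two TE layouts that share an ancestral core (three elements in
conserved type/order/orientation) plus independent insertions on each
side, then finds the maximum order-preserving matching under shared
family AND orientation - the criterion used to compare IGSs between
species.
"""

from rdnakit import te_orthology as te


def mk(family, orientation, start, length):
    return te.TERecord(family=family, name=family.split("/")[-1],
                       orientation=orientation, start=start, end=start + length)


# shared ancestral elements: L1(+), Alu(-), ERVL(+), in this order
igs_a = [mk("LINE/L1", "plus", 1_000, 2_500),
         mk("DNA/hAT", "plus", 4_000, 400),      # A-specific
         mk("SINE/Alu", "minus", 6_000, 300),
         mk("LTR/ERVL", "plus", 9_000, 1_200),
         mk("SINE/Alu", "plus", 12_000, 310)]    # A-specific
igs_b = [mk("SINE/MIR", "minus", 500, 200),      # B-specific
         mk("LINE/L1", "plus", 2_000, 2_300),
         mk("SINE/Alu", "minus", 7_000, 290),
         mk("LINE/L2", "minus", 8_500, 900),     # B-specific
         mk("LTR/ERVL", "plus", 11_000, 1_150)]

matching = te.match_orthologous_tes(igs_a, igs_b)
report = te.orthology_report(matching, igs_a, igs_b,
                             igs_length_a=30_000, igs_length_b=34_000)

print(f"TEs per side        : {report['n_te_a']} vs {report['n_te_b']}")
print(f"orthologous pairs   : {report['n_orthologous']}")
for i, j in matching.pairs:
    a = igs_a[i]
    print(f"  {a.family:<10} {a.orientation:<5} "
          f"{igs_a[i].length:>5} bp ~ {igs_b[j].length:>5} bp")
print(f"orthologous TE bp   : {report['orthologous_bp_a']:,} (A) / "
      f"{report['orthologous_bp_b']:,} (B)")
# Only the three elements conserved in type, order and orientation match;
# lineage-specific insertions stay unpaired.
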