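"""Degenerate promoter design: consensus, enumeration, primer assembly.

Determines the library consensus from a collection of constitutive -35/-10
hexamers under the boundary constraint (-35 ends in A, -10 starts with T,
matching the first/last base of the lux box), enumerates the degenerate
promoter space, assembles the forward library primer and checks the
sequenced members against the consensus.
"""

from luxrep import design

# consensus from a toy constitutive-promoter collection
cons = design.consensus_from_collection(
    [("TTGACA", "TATAAT"), ("TTTACA", "TATTAT"), ("CTGACA", "TACAGT"),
     ("TTGACG", "TATAAT")]  # last one violates the boundary constraint
)
print(f"-35 consensus: {cons.minus35_consensus}  "
      f"-10 consensus: {cons.minus10_consensus}  "
      f"({cons.n_excluded} promoter(s) excluded, "
      f"{cons.cardinality} variants)")

# the shipped library consensus and its 64-promoter space
lib = design.LIBRARY_CONSENSUS
print(f"\nlibrary consensus: {lib.minus35_consensus}-[lux box]-"
      f"{lib.minus10_consensus} -> {len(lib.enumerate_members())} promoters")

primer = design.assemble_degenerate_primer(
    lib, design.PRIMER_PREFIX, design.PRIMER_ANNEAL_TAIL
)
print(f"forward primer: {primer}")
print(f"matches shipped P_LUXH_FWD: {primer == design.P_LUXH_FWD}")

members = design.library_members()
n, _ = design.unique_members(members)
inside = sum(lib.contains(r) for r in members)
print(f"\nsequenced members: {n} unique, {inside}/{len(members)} inside "
      f"the consensus space")
for rec in members[:3]:
    print(f"  {rec.name}: {rec.minus35}-core-{rec.minus10} "
          f"(-35 hexamer {rec.minus35_hexamer}, -10 hexamer {rec.minus10_hexamer})")
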