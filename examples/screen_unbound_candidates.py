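"""Screen sequence-search hits for unbound partner structures.

A complex joins the benchmark only when separately solved (unbound)
structures exist for its components.  Hits from a BLAST-style search are
accepted when identity > 93%, query coverage > 80% and E-value < 1e-5;
per-side availability then yields the pairing state (UU / UB / BU / BB).
"""

from dockbench import categorize_case, collect_unbound_candidates, read_blast_tabular

# BLAST tabular (outfmt 6): qseqid sseqid pident length mismatch gapopen
#                           qstart qend sstart send evalue bitscore
hits_table = """\
H\tu_ab1\t98.3\t118\t2\t0\t1\t118\t1\t118\t3e-80\t240
H\tu_ab2\t95.0\t100\t5\t0\t10\t109\t1\t100\t1e-40\t180
H\tu_weak\t80.0\t118\t24\t0\t1\t118\t1\t118\t1e-30\t120
A\tu_ag_low_cov\t99.0\t60\t1\t0\t1\t60\t1\t60\t1e-30\t130
"""

hits = read_blast_tabular(hits_table, {"H": 120, "A": 150})
ab = {"H": collect_unbound_candidates(hits, "H")}
ag = {"A": collect_unbound_candidates(hits, "A")}

for chain, cands in {**ab, **ag}.items():
    print(f"chain {chain}: {len(cands)} accepted unbound candidate(s): "
          f"{cands.subject_ids()}")

state = categorize_case(ab, ag)
print(f"\npairing state: {state.value}")
print("UB means the antibody has unbound structures but the antigen does not")
print("(u_weak fails the 93% identity bound; the antigen hit covers only")
print("60 of 150 query residues, below the 80% coverage bound).")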