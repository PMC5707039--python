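"""Parse mpileup text into strand-oriented counts and allele observations.

The read-bases string encodes each read's base and orientation; the parser
splits support by strand, which downstream filters rely on to spot
single-orientation artifacts.
"""

from segaloh import allele_observations, parse_pileup

PILEUP = """\
chr9\t135771030\tC\t12\t.,.,.TT,..t,\tIIIIIIIIIIII
chr9\t135771031\tG\t8\t.,.,.,.,\tIIIIIIII
chr9\t135771032\tA\t6\t.+2TC.+2TC,,..\tIIIIII
"""

for counts in parse_pileup(PILEUP.splitlines()):
    print(f"{counts.position.contig}:{counts.position.pos} ref={counts.ref_base} "
          f"fwd={counts.counts_forward} rev={counts.counts_reverse}")
    for obs in allele_observations(counts):
        print(f"  non-reference allele {obs.alt!r}: {obs.count_forward}+/{obs.count_reverse}- "
              f"of {obs.depth_total} reads, fraction {obs.frequency:.3f}")

# The T substitution is seen on both strands (2 forward, 1 reverse) at 25% —
# a plausible variant; the +TC insertion is carried by 2 forward reads only,
# the signature the orientation filter flags.
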