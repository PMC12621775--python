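"""Three canonical toy graphs used throughout the test-suite and docs.

* G1 — a simple bubble (SNP site): 1:"GATT" branches through 2:"A" or
  3:"C" and rejoins at 4:"ACA"; haplotypes hapA (via 2) and hapB (via 3).
* G2 — an inversion: 2:"TTG" can be traversed forward or in reverse
  between 1:"GAT" and 3:"CA".
* G3 — a loop: 2:"CGA" has a back edge onto itself, so walks may traverse
  it multiple times (a tandem duplication).
"""

from .graph import parse_gfa

G1_GFA = """\
S\t1\tGATT
S\t2\tA
S\t3\tC
S\t4\tACA
L\t1\t+\t2\t+\t0M
L\t1\t+\t3\t+\t0M
L\t2\t+\t4\t+\t0M
L\t3\t+\t4\t+\t0M
P\thapA\t1+,2+,4+\t*
P\thapB\t1+,3+,4+\t*
"""

G2_GFA = """\
S\t1\tGAT
S\t2\tTTG
S\t3\tCA
L\t1\t+\t2\t+\t0M
L\t2\t+\t3\t+\t0M
L\t1\t+\t2\t-\t0M
L\t2\t-\t3\t+\t0M
P\thapA\t1+,2+,3+\t*
P\thapB\t1+,2-,3+\t*
"""

G3_GFA = """\
S\t1\tGAT
S\t2\tCGA
S\t3\tTT
L\t1\t+\t2\t+\t0M
L\t2\t+\t2\t+\t0M
L\t2\t+\t3\t+\t0M
P\thapA\t1+,2+,3+\t*
P\thapB\t1+,2+,2+,3+\t*
"""


def g1():
    return parse_gfa(G1_GFA)


def g2():
    return parse_gfa(G2_GFA)


def g3():
    return parse_gfa(G3_GFA)
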