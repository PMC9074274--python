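"""Greedy length-sorted protein clustering at 95% identity.

Three 'species' with near-identical variants plus two unrelated singletons:
the clusterer should find exactly five clusters, each represented by its
longest member.
"""

import random

from mixcat import ClusterParams, greedy_cluster

rng = random.Random(0)
AA = "ACDEFGHIKLMNPQRSTVWY"


def protein(n):
    return "".join(rng.choice(AA) for _ in range(n))


def variant(seq, identity):
    out = list(seq)
    for pos in rng.sample(range(len(seq)), round((1 - identity) * len(seq))):
        out[pos] = rng.choice([a for a in AA if a != out[pos]])
    return "".join(out)


proteins = {}
for s in range(3):
    base = protein(120)
    proteins[f"sp{s}_full"] = base
    proteins[f"sp{s}_variant"] = variant(base, 0.97)     # same species
    proteins[f"sp{s}_fragment"] = variant(base[:70], 0.98)  # assembly fragment
proteins["lone1"] = protein(100)
proteins["lone2"] = protein(90)

clusters = greedy_cluster(proteins, ClusterParams(min_seq_id=0.95, min_member_cov=0.95))
print(f"{len(proteins)} proteins -> {len(clusters)} clusters")
for c in clusters:
    members = ", ".join(sorted(c.member_ids))
    print(f"  rep {c.representative_id} ({len(proteins[c.representative_id])} aa): {members}")

# Each sp* cluster keeps the full-length protein as representative: members
# must be >= 95% identical over >= 95% of their own length, so fragments are
# absorbed while the two unrelated proteins stay singletons.
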