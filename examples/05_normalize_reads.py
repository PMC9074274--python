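"""Digital normalization: downsample deep coverage, drop error reads.

Two genomes at 10x and 200x plus singleton error reads.  Normalizing to a
40x target should leave the abundant genome near 40x, keep the rare genome
intact, and remove the error reads entirely (depth < 2).
"""

import random

from mixcat import NormalizeConfig, kmer_depth_profile, normalize_reads
from mixcat.records import Read, ReadSet

rng = random.Random(0)
make = lambda n: "".join(rng.choice("ACGT") for _ in range(n))
g_rare, g_deep = make(600), make(600)

reads = []
for label, genome, cov in (("rare", g_rare, 10), ("deep", g_deep, 200)):
    n = cov * len(genome) // 100
    for i in range(n):
        pos = rng.randint(0, len(genome) - 100)
        reads.append(Read(f"{label}{i}", genome[pos : pos + 100], 1))
reads += [Read(f"err{i}", make(100), 1) for i in range(40)]

readset = ReadSet("demo", reads)
out = normalize_reads(readset, NormalizeConfig(k=21, target_depth=40, min_depth=2, seed=1))

count = lambda rs, tag: sum(1 for r in rs.reads if r.read_id.startswith(tag))
print(f"{'':6s} {'before':>7s} {'after':>6s}")
for tag in ("rare", "deep", "err"):
    print(f"{tag:6s} {count(readset, tag):7d} {count(out, tag):6d}")

depths = [d for d in kmer_depth_profile(out.reads, 21) if d is not None]
import numpy as np
print(f"\nmedian post-normalization read depth: {np.median(depths):.0f}x "
      f"(target 70 would keep everything; target 40 flattens the deep genome)")
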