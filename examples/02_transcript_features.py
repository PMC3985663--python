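"""Characterize simulated cDNA clones: classes, TSS positions, splice donors.

5' RACE-like clones are generated from the planted fusion transcripts
(19 testis, 35 kidney, 54 brain, plus sense-strand poly(A)+ decoys),
classified, and their antisense transcription start sites mapped onto the
sense-strand coordinates of the L1 reference element.  Antisense TSS
cluster in the tissue-specific windows just downstream of the antisense
promoter in ORF1 (testis 2201-2244).
"""

import riftscan as rs
from riftscan.features import (class_counts, classify_clone,
                               find_splice_donors, map_tss,
                               summarize_donor_usage)

config = rs.GeneratorConfig(seed=1)
annotation = rs.gen_genome(config)
planted = rs.plant_rifts(annotation, config)
clones = rs.gen_transcript_clones(annotation, planted, config)
ref = rs.make_l1_reference(seed=1)

print(class_counts(clones, annotation.l1s).to_string(index=False))
print("(spliced AS = antisense 5' end inside an L1, spliced to downstream"
      " exons; unspliced AS reads through the element 5' end into flank;"
      " premature sense-polyA clones are the decoys)")

as_clones = [c for c in clones
             if classify_clone(c, annotation.l1s).endswith("AS_RIFT")]
for tissue, counter in sorted(map_tss(as_clones, annotation.l1s,
                                      ref).items()):
    lo, hi = min(counter), max(counter)
    print(f"{tissue}: {sum(counter.values())} antisense TSS mapped to L1 "
          f"sense coordinates {lo}-{hi}")

donors = [d for c in clones
          if (d := find_splice_donors(c, annotation.l1s, ref))]
print(summarize_donor_usage(donors).to_string(index=False))
print("(each donor 9-mer = last 4 exonic nt + first 5 intronic nt on the"
      " antisense transcript; canonical donors start the intron with gt)")

hits = rs.scan_atg(ref, ref.landmarks["orf1"])
frames = {frame for _, frame, _ in hits}
print(f"antisense ATG scan across ORF1: {len(hits)} predicted starts in "
      f"{len(frames)} reading frames")
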