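"""Compute the three k-mer feature normalizations for tiny sequences.

tf scales the raw k-mer counts to unit length; tfti additionally
down-weights k-mers that are frequent across the whole reference corpus;
oligo contrasts each observed count against the expectation under an
independent single-nucleotide null model (positive = over-represented,
negative = under-represented, zero = absent).
"""

import hyperbin as hb
from hyperbin.kmers import kmer_index

profile = hb.count_kmers("acgt", k=2)
print(f"'acgt', k=2: total {profile.total} k-mers over "
      f"{profile.seq_length} clean nucleotides")

tf = hb.tf_normalize(profile)
print(f"tf(ac) = {tf.values[kmer_index('ac')]:.5f}  "
      "(each of the 3 observed 2-mers gets 1/sqrt(3))")

s1 = hb.count_kmers("aaa", 2)   # contributes aa twice to the corpus
s2 = hb.count_kmers("aac", 2)   # aa once, ac once
stats = hb.corpus_term_stats([s1, s2])
tfti = hb.tfti_normalize(s2, stats)
print(f"tfti(aa) = {tfti.values[kmer_index('aa')]:.5f}, "
      f"tfti(ac) = {tfti.values[kmer_index('ac')]:.5f}  "
      "(aa is frequent corpus-wide, so its weight drops)")

oligo = hb.oligo_features("acacac", 2)
print(f"oligo(ac) = {oligo.values[kmer_index('ac')]:.4f}, "
      f"oligo(ca) = {oligo.values[kmer_index('ca')]:.4f}, "
      f"oligo(aa) = {oligo.values[kmer_index('aa')]:.1f}  "
      "(ac/ca occur twice/1.3x as often as expected; aa is absent)")
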