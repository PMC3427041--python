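# Methods

This note records the models, numerical choices and known limitations behind
`homeopipe`. It is written for a reader who wants to know exactly what the
package computes and why each open design point was resolved the way it was.

## The simulated study system

`simgen` models a four-genome allopolyploid system on the fixed topology
(((A2, A_T)) , ((D5, D_T))): an ancestral coding sequence splits into the A-
and D-genome ancestors, each diploid lineage (A2, D5) and each allotetraploid
homoeolog (A_T, D_T, independently per tetraploid species) then accumulates
its own terminal-branch substitutions — a star phylogeny within each genome.

**Sequence evolution.** Each contig begins as a random string of sense codons
(no stops). Substitutions are proposed uniformly over sites at a per-site
rate equal to the Jukes–Cantor-inverted target distance, with the
replacement base uniform over the three alternatives (JC-equal exchange).
A proposal is accepted with probability 1 if synonymous and `dnds`
(default 0.3) if nonsynonymous; proposals creating a stop codon are always
rejected, so sequences stay coding. Because accepted synonymous changes per
synonymous site then equal the proposal rate in expectation, the realized
NG86 dS lands on the target without further tuning (measured: 0.0362 at a
0.036 target over 500 contigs). Realized dN sits slightly below
`dnds × dS` because of the stop-codon rejection; nothing downstream depends
on its exact value.

**Divergence bookkeeping.** `target_dS_AD` (default 0.036) is the *total*
A2-vs-D5 synonymous distance. The two ancestral half-branches therefore each
receive `(target_dS_AD − b_A2 − b_D5)/2`, where `branch_dS` (defaults
A2 0.005, AT 0.006, D5 0.009, DT 0.010 substitutions per synonymous site)
are per-lineage terminal branch rates. This also fixes the tetraploid
inter-genomic distance at `target − b_A2 − b_D5 + b_AT + b_DT ≈ 0.038`,
matching the observed ordering (tetraploid pair slightly more diverged than
the diploid pair). One consequence to keep in mind: published intra-genomic
*pairwise* distances of ~0.005–0.010 correspond to branch sums here, so the
simulated pairwise A2-vs-A_T distance is roughly twice that; the
lineage-rate *direction* (A2 < A_T, D5 < D_T), which is what the polarization
analysis tests, is unaffected.

**NRHR tracts.** A contig carries a conversion event with probability
`nrhr_contig_frac` (default 0.07). Tract length is geometric with mean
`nrhr_tract_len_mean` (default 150 bp — a modeling choice; no tract-length
distribution is established for this system). With probability
`nrhr_shared_frac` (default 0.23) the event is ancestral and applied to both
tetraploid species at identical coordinates; otherwise one species is chosen
uniformly, as is the direction (A→D or D→A). Placement is rejection-sampled
so the tract covers ≥ 2 true diagnostic sites and leaves ≥ 1 outside — the
regime in which an event is detectable from reads at all.

**Reads.** Coverage is per genome copy (six copies per contig: A2, D5 and
two homoeologs in each of two tetraploid species). Long reads are uniform
250–450 bp, short reads 82 bp; starts are uniform with reads fully inside
the contig, so depth dips toward contig ends. Per-base qualities come from a
two-class mixture (Q40 / Q12) whose weight reproduces the configured mean
error rate; errors are drawn per base at the class rate and substitute a
uniformly random other base. Both platforms carry qualities (the long-read
technologies being emulated report them too). Identical `SimConfig`s give
byte-identical output files.

**What is not emulated.** Indels and homopolymer-specific error modes,
expression-level variation (every genome copy is sampled at the same
coverage), alternative splicing, allelic (within-genome) polymorphism, and
assembly artifacts. Passing tests on this generator therefore demonstrate
correctness of the algorithms under substitution-only evolution with
uniform sampling — not robustness to misassembly or allelic variation,
which on real data are additional false-positive sources.

## Consensus and SNP calling

Columns are majority-rule: a column is masked when depth < `min_depth`
(default 2, the minimal evidence for a consensus), when the major allele is
tied, or when its frequency is not strictly greater than `min_major_freq`
(default 0.90). Ties mask conservatively.

The **assembly caller** proceeds per contig: diploid consensuses from long
reads → candidate sites where both are unmasked and differ → candidate
refinement → tetraploid read partitioning → tetraploid subgenome consensuses
→ emit sites where the tetraploid consensuses differ and equal the diploid
allele pair. Two steps deserve justification:

* *Candidate refinement.* Diploid-difference columns include diploid
  lineage-specific mutations, which are not genome-diagnostic: every
  tetraploid read carries the single ancestral allele there. Each candidate
  must therefore show both parental alleles among tetraploid long reads
  (≥ `min_depth` reads each). Without this, local clusters of diploid branch
  mutations can outvote the true diagnostic sites and flip entire reads into
  the wrong subgenome pool.
* *Majority-vote pooling.* Reads are pooled by vote majority rather than by
  the strict all-A/all-D classes (which remain available from
  `assign_read` for reporting): residual non-diagnostic sites put stray
  opposite votes on reads, and discarding every such read would empty the
  pools. Any site whose tetraploid alleles contradict the diploid pair is
  still rejected at the consensus-match stage.

The **pileup caller** scores each short-read column with a posterior over
ten states — four fixed bases and six balanced two-allele mixtures — under a
per-base error model (correct with probability 1−ε, ε = 0.01 by default,
otherwise uniform on the other bases) and a uniform prior. The call quality
is −10·log₁₀ P(consensus wrong); calls require the best state to be a fixed
base with quality ≥ 20 in both diploid groups. The mixture states are the
point of the model: at depth 2 a fixed base cannot be distinguished from a
within-group polymorphism (quality ≈ 3.7), so thin columns are not called,
while 30 clean reads yield quality ≈ 85. Roughly nine concordant reads are
needed to reach quality 20.

**Confirmation** marks a SNP confirmed when at least one tetraploid read
carries each parental allele at the site — the guard against diploid
lineage-specific mutation and tetraploid homoeolog loss. **Reconciliation**
keys SNPs by (contig, position); common calls agree when the oriented allele
pair matches, and the union is computed by inclusion–exclusion. Disagreeing
calls are flagged, never silently dropped.

## NRHR detection

Detection works on the *diploid* diagnostic-site list, not the
tetraploid-confirmed subset: a shared (ancestral) conversion removes one
parental allele from both tetraploids, so confirmed sites can never witness
shared events. Chimeric tetraploid reads (both an A and a D state among
their high-quality diagnostic bases; states below phred 20 are dropped) are
binned per species into connected components of the pairwise
share-or-extend graph: two reads join when they overlap at ≥ 1 site and
agree at every shared site. The component haplotype is the per-site majority
over its reads; chain-induced disagreements (possible through intermediate
reads even though no merged pair conflicts directly) are resolved by
majority and flagged rather than treated as impossible. Binning is invariant
under read input order. Events from the two species merge as *shared* when
they agree at every diagnostic site present in both (sites covered in only
one species are ignored — read sampling differs per species); shared
placements carry a parallel-mutation caveat flag, mirroring the fact that
the data cannot exclude independent identical exchanges.

Two guards sit on top of the binning, both designed from an error analysis
rather than fitted to any outcome:

* `min_support` (default 2 reads per event): one read cannot distinguish a
  tract from a read-level artifact; an error collision across two
  independent reads is quadratically unlikely.
* `min_state_sites` (default 2) with a contiguity condition: both genome
  states must appear at ≥ 2 haplotype sites, and at least one state must
  occupy a single contiguous block. A conversion tract is an interval; a
  single opposite-genome site — or two scattered ones — is indistinguishable
  from point substitutions arisen after polyploid formation (autapomorphic
  homoplasy). A side effect is that a closure class in which *both* states
  are split (a putative multi-tract "complex event") is conservatively not
  reported.

**The homoplasy channel.** With realistic post-polyploid branch evolution, a
diploid branch substitution produces exactly the same fixed-difference
observable as a one-site shared conversion (three genomes unanimous, one
divergent), and two *adjacent* such sites are observationally identical to a
two-site shared tract. No detector can separate these cases from fixed
differences alone; the test suite pins the behaviour with a constructed
fixture. This is precisely the false-positive class that the external
validation-rate correction (`estimate_true_rate`, default 0.70) models:
corrected rate = validation_rate × affected contigs / total contigs.
Detector-performance experiments (recall/precision/placement ≥ 0.9, zero
events on the error-free conversion-free control) are therefore run under
divergence+NRHR-only evolution, where the channel is absent by construction;
under full default branch rates the correction, not the detector, carries
the burden.

## Molecular evolution

NG86 counting: synonymous site counts per codon are the per-position
fractions of single-base changes preserving the amino acid (changes to stop
codons count as nonsynonymous), averaged over the two sequences.
Multi-difference codons average Sd/Nd with equal weights over all orderings
of single-step pathways; orderings through an intermediate stop codon are
excluded, and if every ordering is blocked all are kept so the estimate
stays defined. No transition/transversion weighting. Proportions are
JC-corrected; p ≥ 0.75 is reported as undefined rather than clamped.

Alignment filtering: in-frame overlap of the two (possibly masked)
consensuses; any codon containing a masked or ambiguous base is removed
*before* the 198-bp minimum-length test (the stricter of the two possible
orders); contigs with a detected NRHR event are excluded upstream. Survey
summaries are unweighted per-contig means and standard deviations
(length-weighted pooling is available via `pooled_ng86`); dN/dS ratio
summaries exclude contigs with zero or undefined dS, where the ratio does
not exist.

Polarization counts a quartet column for a lineage only when that lineage
differs and the other three are unanimous; columns with ≥ 2 derived states
are discarded, and only columns with all four states unambiguous enter the
nucleotide total. The binomial test is exact and two-sided by doubling the
smaller tail (capped at 1) — the conservative choice where sidedness is
unspecified. The Wilcoxon signed-rank test drops zero differences,
mid-ranks ties, uses the exact null for n ≤ 25 without ties and the normal
approximation with continuity correction otherwise, pairs by contig id, and
requires ≥ 6 non-zero differences (identical vectors return p = 1).

## Problem sizes and tolerances in the test suite

Calibration checks use 500 contigs (~0.45 Mb) for the ±15% divergence
recovery and 3,600 contigs (~3.2 Mb per quartet) for the lineage-direction
binomials; NRHR recovery uses 200 contigs at 20× long-read coverage and
0.005 error; exact SNP recovery uses 40 error-free contigs at 14× with the
evaluation restricted to sites at per-species depth ≥ 10 (shotgun edge
columns below the consensus depth floor are masked by design). The NG86
implementation is checked against an independently written brute-force
pathway-enumeration oracle on 1,000 random codon pairs. All simulations are
seeded; hypothesis-based property tests run derandomized.

## Known limitations

* Event counting reports closure classes; whether a multi-event contig holds
  independent exchanges or one unresolvable complex event is left to the
  user, and both-states-split classes are not reported at all (see above).
* The pileup quality model assumes a uniform per-base error rate rather than
  using the reads' own qualities; it is a documented stand-alone model, not
  a reimplementation of any particular pileup tool's score.
* `estimate_true_rate` treats the validation rate as external truth; it is
  not estimated from the data.
* Frames are taken as given (`frames.tsv`; frame 0 in simulation). No ORF
  prediction is performed.
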