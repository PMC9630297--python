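# Methods

This note documents the models, parameter choices and numerical decisions
behind the toolkit, and what its passing tests do and do not demonstrate.

## Secret sharing

The (2,3)-threshold scheme operates on byte strings.  An odd-length
secret is padded with one trailing zero byte; the pre-padding length is
recorded in the container metadata and reconstruction truncates to it.
Halving is contiguous (S₁ = first half, S₂ = second half), matching the
concatenation notation of the share formulas.  XOR runs over numpy
`uint8` views, so splitting and reconstruction are memory-bandwidth
bound.

Large inputs stream chunk-by-chunk (default chunk 64 MiB, configurable);
each chunk is split independently with fresh randomness.  The container
format is bespoke and bit-exact: magic `DSGD`, version, share id, flags,
chunk size, original length, chunk count, and a CRC-32 of the metadata,
followed by `half1 ∥ half2` per chunk.  Metadata is stored in the clear
in all three containers — share and OTP schemes inherently leak length,
and we document rather than disguise that.

Randomness is injected as a callable `rng(n) -> bytes`.  In pipeline mode
the default draws from the simulated QKD key supply (the design requires
keys from a non-periodic physical source); standalone callers get the OS
CSPRNG; tests and the demo use a seeded SHAKE-256 counter-mode stream so
artifacts are bit-identical across runs.

Secrecy is verified *exhaustively at 4-bit scale*: for every secret, each
single share cycles through all 16 possible values exactly once as the
randomness does — a counting proof of perfect secrecy for that size, and
the algebra is size-independent.  An independent brute-force oracle of
the printed formulas pins all 256 nibble combinations.

## Key network

The quantum layer is modelled as seeded random bytes delivered
identically to both endpoints of a link; there is no photonic or
error-rate modelling, so tests say nothing about QKD hardware — only
about the management layer above it.  Key relay generates a fresh key at
the source and forwards it hop-by-hop, OTP-encrypted under each link's
key; intermediate nodes transiently see the key, which is precisely the
trusted-node assumption.  Routing is shortest-path by hop count with
lexicographic tie-breaking (the deployment's policy is not specified
anywhere authoritative, so we fix a deterministic one).

Accounting is byte-exact: per link, `generated = available + reserved +
consumed + erased` after every operation; erroring operations are atomic
(checked before any mutation).  The two endpoint copies of a link or
relay key are tied together and consumed or erased in lockstep — they are
one logical key, so no byte can be supplied twice, which a property test
drives with random operation sequences.  `supply_key` hands bytes to a
service-layer consumer and erases the network-side copy; from that point
responsibility lies with the consumer, mirrored in code by the
`OtpKeystream` contract below.

The default topology mirrors the reference deployment: a data owner
co-located with the trusted server (also a share holder), two further
share holders, one user endpoint, all reachable within two hops.

## OTP and authentication

`OtpKeystream` wraps key material with a forward-only offset; consumed
bytes are zeroized immediately.  `clone()` exists to model the *peer's*
identical copy of QKD-supplied key material (sender encrypts, receiver
decrypts); it is not key reuse by one party, and the single-use tests
cover the one-party contract.

Wegman–Carter tags use the polynomial-evaluation hash H = Σᵢ mᵢhⁱ over
GF(2^w) on zero-padded w-bit blocks, masked with fresh OTP bytes.
Supported widths are 8 (for exhaustive testing), 64 and 128 (default;
reducing polynomial x¹²⁸+x⁷+x²+x+1).  For same-length messages of n
blocks the collision probability over a uniform hash key is ≤ n/2^w,
which the suite verifies by enumerating all 256 keys at w = 8.  Zero
padding makes messages that differ only by trailing zero blocks collide;
the pipeline therefore authenticates fixed-framing ciphertexts whose
length is bound to the session, and the limitation is stated here rather
than patched with a nonstandard construction.  A process-wide registry
rejects reuse of a (hash key, mask) pair — with one-time keys the bound
is information-theoretic; with reused keys it is void.

The key lifecycle derives K₄ = K₁⊕K₃ where K₃ is an AES-128-CTR
keystream (counter from zero, big-endian) seeded by the 16-byte K₂; the
split point defaults to "last 16 bytes are K₂", honouring
size(K₁) ≫ size(K₂).  AES-128 is implemented in-package (encrypt-only,
pinned to the FIPS-197 appendix vector) because it is used purely as a
deterministic expander; pure-Python throughput (~0.5 MB/s) is ample for
the delivery-sized keys this role needs.  The expansion step is
computationally, not information-theoretically, secure — the design
accepts this for the stored-medium attack only, and the software contract
is the testable part: after erasing short-term components (step 4) and
then the long-term part (step 5, order enforced), every component access
raises, and K₄ cannot be recomputed from K₁ alone.  Erasure in a managed
runtime is best-effort overwrite plus API inaccessibility; it is a
logical contract, not a physical guarantee.

## VCF disclosure

Filtering is a single pass over the text stream, so plain and gzip input
behave identically and header lines survive byte-for-byte; exactly one
provenance header line is added, and never duplicated, which makes
filtering idempotent.  Five modes cover the ways "extract N cases" can be
read — nothing, first-N in file order (deterministic), 1-based inclusive
regions (merged and sorted at normalisation), an explicit variant-ID
list, or everything — plus INFO/FORMAT allow-lists; masking every FORMAT
key releases site-level columns only.  Records are never split or
normalised; multi-allelic and symbolic-ALT records pass or fail as whole
records.  The htslib parser (pysam) serves as an independent oracle in
tests for counts and region membership, never as the filter itself.

## Synthetic fixtures and the toy caller

The generators stand in for patient-scale inputs (a real FASTQ is tens of
GB; a real VCF has ~3–4 million records) at roughly 1:1000 scale: a
uniform-random reference (1+ chromosomes, ≥ 1 kb), substitution-only
planted variants (hom on both haplotypes, het on one), fixed-length
error-free reads tiling each haplotype uniformly so coverage is exact and
deterministic, and standalone sorted VCFs of any record count.  Variant
density is capped at one per 20 bp to keep reads anchorable.  All
text/gzip output is byte-stable under a fixed seed (gzip mtime pinned to
zero, no embedded filenames, no locale- or float-formatting dependence).

The toy caller anchors each read by exact 20-mer lookup, extends to the
Hamming-nearest placement, accumulates per-column base counts, and emits
a substitution call where a non-reference allele reaches fraction ≥ 0.25
at depth ≥ 4 (hom if ≥ 0.75, else het), ordered by (chromosome,
position).  With the generator's error-free reads at coverage ≥ 10 this
recovers the planted truth set exactly — recall = precision = 1.0 — which
is the property the pipeline tests rely on.  The thresholds are fixture
constants; nothing here claims accuracy on real sequencing data, where
errors, indels, repeats and mapping ambiguity dominate.

## Pipeline

All nodes run in one process over an in-memory transport that records
every message (tests tap it to assert that no plaintext crosses between
nodes in secure mode).  The variant caller is a plugin taking FASTQ.gz
bytes and a reference and returning VCF.gz bytes: the built-in toy caller
is the default, and a replay plugin carries a pregenerated VCF for
disclosure-scenario runs where the calling engine's output is fixed — the
protocol treats the engine as a black box either way.  Share fetch on a
request goes to the lowest-node-id holder.  The protected area bounds
transient plaintext (1 GiB, 24 h TTL against an injectable clock) and is
purged at the end of every session, including error paths.

Stage timings use wall-clock `perf_counter` with a 1 µs floor so the
metric formulas are always defined; the five throughputs are then pure
arithmetic over recorded sizes and times, and a recompute method makes
the identity testable.  Absolute Mbit/s values from the demo reflect this
implementation on desk-scale inputs and are reported, not asserted —
hardware throughput is explicitly out of scope.  The one quantitative
anchor asserted is arithmetic: 22,676 MB of FASTQ over 352.5 s is
514.6 Mbit/s under the MB = 10⁶ convention, rounding to the published
515.

Demo problem sizes are the package's own choice for exhaustive desk-scale
verification: a 50 kb reference, 10,000 reads (100 bp, 20×), 50 planted
variants, and 3,000-record VCFs with disclosure scenarios
0 / 30 / 1,500 / 3,000 — the published extraction scenarios at 1:1000.

## Known limitations

- Perfect-secrecy and collision bounds are verified exhaustively only at
  reduced widths (4-bit secrets, GF(2⁸)); larger widths inherit the
  algebra but are spot-checked, not enumerated.
- The QKD layer is an idealised key source; availability, error rates and
  authentication of the key-management channel itself are not modelled.
- Erasure cannot defeat a memory forensics adversary inside the same
  process; it enforces the protocol's logical lifecycle.
- The zero-padding length-extension caveat of the universal hash applies
  when callers authenticate variable-length messages without framing.
- The toy caller handles substitutions only and requires anchorable,
  near-error-free reads.
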