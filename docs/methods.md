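# Methods

## The curation-database model

Conventional DICOM databases normalize to the standard's entity model
(Patient → Study → Series → Instance) and must reject or coerce files that
violate it.  This package inverts that: the schema normalizes to the
*encoding structure* of each file.  A file record carries the six entity
keys as plain nullable columns, a whole-file MD5, a pixel-payload MD5, and
positional attributes; an element table holds one row per element
occurrence (sequence items included, addressed by paths like
`3006,0010[0]/0020,0052`).  Nothing enforces hierarchy or uniqueness across
files, so a series claiming two studies, per-slice Frame of Reference UIDs,
or an empty Patient ID are all representable — and findable by query.

The only rejection path is a stream that cannot be framed into elements.
Concretely: the underlying parser is run in force mode, then every raw
element's declared length is checked against the bytes actually read
(truncation inside a value), and the stream must show either the `DICM`
magic or at least one standard data element (group ≥ 0008) known to the
dictionary — force-reading zero padding otherwise fabricates empty
group-0000 elements.  Everything else (missing Type-1 attributes, invalid
values, broken hierarchies) parses and is recorded as notes.

Values are compared as raw bytes after stripping at most one trailing pad
byte (space or NUL).  No transcoding or character-set normalization is
applied during comparison: hiding a real clash behind normalization would
produce false repairs.  Empty (`""`, zero-length element) and absent are
deliberately distinct states throughout.

## Pixel digests

The digest input is the stored value field of the pixel-data element
(7FE0,0010) exactly as encoded; for encapsulated transfer syntaxes, the
concatenated fragment payloads excluding item headers and the basic offset
table.  Digesting stored bytes rather than decoded pixels keeps the
identity test byte-exact and decoding-free: two files match iff their
stored payloads match.  The consequence is that the same image re-encoded
under a different transfer syntax does *not* match — re-encoded or
re-windowed duplicates are out of scope by design.  MD5 is the default
algorithm (the field's conventional choice for this purpose; collision
probability is irrelevant at curation scale) and is configurable.

## Consistency checking and repair policies

A ruleset lists, per entity level, the attributes expected to be
single-valued across the entity's files.  The shipped default covers
patient identity/demographics (0010,0010; 0010,0020; 0010,0030; 0010,0040;
0010,1030), study identity (0008,0020; 0008,0030; 0008,1030; 0008,0050)
and series identity/geometry (0008,0060; 0008,103E; 0020,0052; 0018,0015;
0008,0021).  The true attribute set a given archive cares about is site
policy, not ground truth, so the ruleset is configuration (YAML) and tests
pass explicit rulesets.

A finding is an entity×attribute with ≥ 2 value buckets.  Repair policies:
**majority** (most frequent non-absent value; ties to the lexicographically
smallest — determinism matters more than the tie choice), **first_file**
(value of the lowest-Instance-Number file, import order as fallback;
if the first file lacks the attribute the proposal deletes it elsewhere),
**manual**.  When every file has its own value (bucket count = file count),
the finding carries a `per_file_descriptions` flag: this is the
"per-image Series Description" pathology, where any single-value repair
destroys information, so the flag marks the finding for human judgement;
no migration edit (e.g. into Image Comments) is generated.

Proposals are never auto-applied.  Applying a proposal routes through the
revision manager, and a re-scan afterwards is empty for the repaired tags
(the fixpoint property asserted in tests).

## Revisions

The file store is content-addressed (objects keyed by whole-file MD5), so a
revision is just a list of digest references: copy-on-write is free,
rollback is a pointer move, identical rewrites deduplicate, and the store
is tamper-evident.  Locks are a database row with an expiry timestamp
(default 1 h) — the contract is single-writer per subject, not a particular
mechanism.  A failed edit (unknown target, malformed path, index out of
range) creates nothing: targets and paths are validated and all rewrites
performed in memory before any database write, and the transaction commits
last.  Rolling back and editing again branches the revision graph; both
branches stay in the log with full audit metadata.  An edit whose result
equals existing bytes still creates a revision (with an empty diff) so the
audit trail records that the operation happened.

## Duplicate analysis and proto-series inference

- **Digest groups**: digests with ≥ m files, annotated with the containing
  collection/site/subject/series and z-offset per file.
- **Distinguished digests** are excluded from candidate analysis:
  *blank* (payload is one repeated byte value — blank images of a given
  size all hash identically), *manual* (user blocklist), and a
  *test-pattern* heuristic for digests in ≥ 50 files across ≥ 10 subjects
  (defaults; both configurable).  Small duplicate groups such as copied
  key/scout images are deliberately not special-cased — they surface for
  human review.
- **Candidate duplicate series**: digests of one exact multiplicity m,
  grouped by the set of series containing them; series sets sharing many
  such digests are the candidates.
- **Series comparison**: shared-digest counts and the offset shift
  `z_B − z_A`, reported as consistent when all per-digest shifts agree
  within 1e-3 mm.  Offsets come from the third component of Image Position
  (Patient), falling back to Slice Location; DICOM stores these as decimal
  strings, so fixtures are exact and the tolerance is tight.  Offsets are
  rounded to six decimals.
- **Proto inference**: pairwise consistent shifts form a graph that must be
  connected (else `DisconnectedSet`; disagreement raises
  `InconsistentShift`).  Per-series frame positions accumulate breadth-
  first, cycles are checked for closure within tolerance, and the union of
  digests is sorted by aligned offset.  The anchor is the series containing
  the topmost aligned image: submitted series renumber their offsets to end
  at 0, so the series reaching the original's last slice is exactly the one
  whose offsets required no change; ties break to the largest series, then
  lexicographic UID.  Per-series membership must form a contiguous run in
  the proto order; violations are flagged rather than fatal.

Conservation holds by construction and is asserted in tests: distinct proto
images plus per-image overcounts equal total files (206 + 375 = 581 in the
worked example).

## The synthetic generators

The generators produce deterministic, byte-identical Part 10 files
(explicit-VR little-endian, 64×64 16-bit pixels from a PRNG keyed by
`(seed, image index)`, fixed dates, UIDs under a reserved test root).  They
emulate the *structure* of curation problems: entity-attribute bucket
plans (including absent-value buckets and per-slice unique values), blank
images of several sizes, and overlapping duplicated series cut from a
common proto (proto offsets −(n−1)..0 mm at 1 mm spacing, each submitted
series renumbered to end at 0).  The worked example uses the slicings
195/187/199 over a 206-image proto; randomized recovery fixtures draw proto
lengths 20–300 and 2–4 slices, always including one reaching the proto's
tail, redrawn until the shared-image graph is connected.

What they do **not** emulate: real scanner metadata diversity, compressed
transfer syntaxes, non-image SOP classes with referential links,
perceptually-similar-but-re-encoded pixels, or character-set variety.
Passing tests therefore demonstrate the correctness of the bookkeeping and
inference machinery, not robustness to every real-world encoding quirk.

## Numerical and design choices

- Alignment tolerance 1e-3 mm; offsets rounded to 6 decimals before
  comparison (text-encoded decimals are exact in fixtures).
- Serialization targets explicit-VR little-endian; implicit-VR or
  big-endian inputs parse and convert on write, so their round-trip is
  semantic rather than byte-wise.  Unmutated files always re-serialize to
  their original bytes.
- Nicknames are kind-prefixed zero-padded counters (`F000001`, `SE0001`,
  `ST01`) in assignment order — deterministic and ≤ 12 characters; they are
  subject-scoped and never reassigned.
- Validator message normalization masks double-quoted values, dotted
  numeric UIDs and absolute paths, keeping tags and message skeletons; the
  dialect parsed is the `Error - ` / `Warning - ` line convention, with
  unrecognized lines kept verbatim as warnings.
- Problem sizes in the test suite (581-file worked example, ≤ 200-file
  consistency oracles, 50 randomized recovery layouts, 20-edit random
  sequences) are chosen as representative desk-scale workloads; the whole
  suite runs in well under a minute.

## Known limitations

- Duplicate detection is exact-match only; no perceptual similarity.
- Diff pairing uses SOP Instance UID (nickname fallback); an edit that
  rewrites SOP Instance UIDs pairs files as removed+added rather than
  changed.
- The element table stores sequence contents but queries target top-level
  attributes; consistency rules on nested elements are not yet expressible
  in a ruleset.
- Branch merge, multi-subject transactions, and DICOM network services are
  out of scope.
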