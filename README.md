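# dicom-curator

A curation toolkit for DICOM image archives, built around a *curation
database* that records "DICOM as it is" rather than "DICOM as it should
be".  It is aimed at people who maintain shared medical-image collections —
archive curators who receive multi-site, repeatedly de-identified
submissions and have to diagnose broken headers, repair them in bulk with a
full audit trail, and hunt down accidentally duplicated patient data.

## What it does

**Permissive intake.** Every parseable DICOM Part 10 file is imported; only
streams broken beyond element framing are rejected.  Entity keys (Patient
ID, Study/Series/SOP Instance UIDs, Frame of Reference UID) are stored as
plain columns with *no* hierarchy or uniqueness constraints, so
nonconformance becomes a queryable fact instead of a quarantine event.
Each file's elements are stored row-per-occurrence, and every image is
normalized by the MD5 digest of its stored pixel payload.

**Consistency diagnosis.** An entity attribute (say, Frame of Reference UID
at the series level) is consistent when all files of the entity agree.  The
scanner buckets raw values — with "absent" as its own bucket, distinct from
an empty string — across all subjects at once and auto-formulates candidate
bulk edits (majority value, first-file value, or manual), which are applied
only after review.

**Revision-tracked editing.** Edits go through a transaction manager: a
per-subject lock, a declarative JSON edit specification, and a new
immutable revision whose file set is copy-on-write against a
content-addressed store.  Revisions record who/when/what, diff down to the
element level, and roll back by moving a head pointer — history is never
deleted.

**Duplicate and proto-series analysis.** Identical pixel payloads share a
digest, so duplicated images are found by grouping, regardless of UIDs.  A
histogram of digest multiplicities flags candidate duplicated series; pair
comparison recovers the constant z-offset shift between overlapping series;
and a set of overlapping series can be aligned into the *proto series* they
were all cut from.  For images at z-offsets `z_i`, two series `A`, `B`
sharing images match when `z_B(d) − z_A(d)` is constant (±1e-3 mm) over
shared digests `d`; the proto is the union of distinct digests ordered by
aligned offset, anchored on the series whose offsets need no renumbering.

**Validator clustering.** An external conformance validator (e.g.
`dciodvfy`) is run on the first file of every series; its findings are
normalized (values/UIDs/paths masked) and series are partitioned by their
exact finding set, giving a handful of reviewable clusters instead of
thousands of lines.

## Worked example

The bundled generator reproduces a classic curation puzzle: one original CT
series of 206 slices at z-offsets −205..0 mm was submitted three times as
overlapping, renumbered series (195, 187 and 199 files — 581 in all).

```sh
curator --workspace ws fixtures fig8 --seed 1 --out fig8
curator --workspace ws import fig8/S1 -c DUPTEST -s SUBJ1
curator --workspace ws import fig8/S2 -c DUPTEST -s SUBJ2
curator --workspace ws import fig8/S3 -c DUPTEST -s SUBJ3
curator --workspace ws dupes hist
```

prints

```json
{
 "1": 17,
 "2": 3,
 "3": 186
}
```

— 186 pixel digests occur in exactly three files each: the fingerprint of
a series duplicated twice.  Asking which series share those digests and
aligning them:

```sh
curator --workspace ws dupes candidates -m 3
curator --workspace ws dupes proto <the three series UIDs> --out proto.json
```

yields one candidate set of three series sharing 186 digests, and a
reconstructed proto series of **206** distinct images spanning offsets
**−205..0**, with the third series as the anchor whose offsets needed no
renumbering.  `python examples/03_duplicate_series_proto.py` runs the same
analysis from Python and prints each step.

## Layout

- `src/dicom_curator/` — library modules: `model` (parse/digest/mutate),
  `db` (workspace database), `consistency`, `revisions`, `duplicates`,
  `validator`, `fixtures` (synthetic data), `cli`.
- `examples/` — narrative scripts, one per capability.
- `docs/methods.md` — models, parameters, numerical choices, limitations.
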