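"""Exception hierarchy for the curation toolkit.

Only :class:`UnparseableStream` ever rejects input data; every other error
signals a misuse of the API (bad path, unknown revision, ...) rather than a
judgement about the DICOM content itself.
"""


class CuratorError(Exception):
    """Base class for all toolkit errors."""


class UnparseableStream(CuratorError):
    """The byte stream cannot be framed into DICOM elements at all.

    This is the single rejection path of the intake model: files that are
    merely nonconformant (missing required attributes, odd VRs, broken
    entity hierarchies) parse fine and are recorded with notes.
    """


class BadPath(CuratorError):
    """An element path is malformed or does not address a sequence."""


class SequenceIndexOutOfRange(CuratorError):
    """An element path indexes past the end of a sequence."""


class UnknownSubject(CuratorError):
    """The subject has no imported files in this workspace."""


class SubjectLocked(CuratorError):
    """Another live edit handle holds the subject; retry later."""


class UnresolvedTarget(CuratorError):
    """An edit specification names files that do not resolve under head."""


class RevisionNotFound(CuratorError):
    """The requested revision does not exist for this subject."""


class NoNonAbsentValue(CuratorError):
    """A fix cannot be proposed because every bucket is value-less."""


class InconsistentShift(CuratorError):
    """Pairwise slice-offset shifts disagree beyond tolerance."""


class DisconnectedSet(CuratorError):
    """The series set cannot be aligned: the shared-image graph is disconnected."""


class CommandNotFound(CuratorError):
    """The external validator executable is unavailable and no captured
    output was supplied."""
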