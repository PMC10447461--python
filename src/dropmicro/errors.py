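"""Exception hierarchy for the toolkit."""


class DropmicroError(Exception):
    """Base class for all toolkit errors."""


class ParseError(DropmicroError):
    """A file violated its format contract (malformed FASTQ record, GTF gene
    without an identifier, inverted coordinates, ...)."""


class CapacityError(DropmicroError):
    """A combinatorial request cannot be satisfied (segment set infeasible at
    the requested length/distance, more cells than whitelist barcodes, ...)."""


class DesignError(DropmicroError):
    """A bead-primer design is internally inconsistent."""


class InsufficientDataError(DropmicroError):
    """Too little data to run an operation (too few barcodes for a knee,
    no qualifying transcripts for coverage, <2 species for a barnyard, ...)."""
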