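"""Exception and warning types used across morphorec."""


class MorphorecError(Exception):
    """Base class for all morphorec errors."""


class ParseError(MorphorecError):
    """A landmark file could not be parsed (malformed record, bad cell)."""


class SchemaError(MorphorecError):
    """A tabular landmark file is missing required columns."""


class DatasetError(MorphorecError):
    """A dataset-level invariant is violated (mixed k, duplicate ids, empty)."""


class DegenerateShapeError(MorphorecError):
    """A configuration is too degenerate (rank < 2, duplicates) to process."""


class DegenerateShapeWarning(UserWarning):
    """A configuration is degenerate but a defined value can be returned."""


class ConvergenceWarning(UserWarning):
    """An iterative routine stopped at max_iter without meeting tolerance."""
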