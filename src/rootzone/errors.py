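"""Exception hierarchy.

``ValidationError`` covers malformed domain values and profiles, with
``SchemaError`` and ``AlignmentError`` specialising tabular and raster input
problems. ``EvaluationError`` signals that a computation could not proceed
(e.g. a pedotransfer input is missing).
"""


class ValidationError(ValueError):
    """A domain value or profile violates an invariant."""


class SchemaError(ValidationError):
    """A tabular input lacks required columns or has an unusable layout."""


class AlignmentError(ValidationError):
    """Raster layers do not share grid shape, cell size, origin or nodata."""


class EvaluationError(RuntimeError):
    """An evaluation step cannot be computed from the available inputs."""
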