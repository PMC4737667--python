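"""Exception hierarchy.

All package errors derive from :class:`SparseNetsError` so callers can catch
one base class; the mixin standard-library bases keep ``except ValueError``
style code working.
"""


class SparseNetsError(Exception):
    """Base class for all sparsenets errors."""


class ShapeError(SparseNetsError, ValueError):
    """Array dimensions are inconsistent (image vs mask, signal vs dictionary)."""


class InsufficientDataError(SparseNetsError, ValueError):
    """Not enough usable data: too few time points, empty mask, n < k, ..."""


class PlacementError(SparseNetsError, RuntimeError):
    """Synthetic network blobs could not be placed under the overlap constraint."""
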