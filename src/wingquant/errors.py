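"""Exception hierarchy for the wingquant pipeline.

Every pipeline failure raises a subclass of :class:`WingquantError` so batch
drivers can catch pipeline problems without masking programming errors.
"""


class WingquantError(Exception):
    """Base class for all wingquant errors."""


class InputError(WingquantError):
    """A file could not be read or referenced a missing path."""


class ValidationError(WingquantError):
    """An in-memory value violated a contract (shape, range, parameter)."""


class NoDiscFoundError(WingquantError):
    """No filled component passed the minimum-area criterion.

    Carries ``largest_fraction``, the area fraction of the largest component
    that *was* observed, so callers can tune ``min_area_fraction``.
    """

    def __init__(self, largest_fraction: float):
        self.largest_fraction = float(largest_fraction)
        super().__init__(
            f"no disc found: largest filled component covers "
            f"{self.largest_fraction:.4f} of the image"
        )


class NoBimodalityError(WingquantError):
    """The pooled intensity histogram has no spread to threshold."""


class DegenerateGroupsError(WingquantError):
    """A two-sample test was requested on degenerate data."""


class BatchError(WingquantError):
    """Every image in a batch failed."""
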