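"""Exception hierarchy.

All package errors derive from :class:`CombifitError`.  Input/validation
problems (bad tables, bad configuration, missing files) raise
:class:`InputError`; numerical failures during model fitting raise
:class:`FitError`.  The CLI maps these to exit codes 2 and 3 respectively.
"""


class CombifitError(Exception):
    """Base class for all combifit errors."""


class InputError(CombifitError, ValueError):
    """Invalid input data, configuration or file path."""


class DesignError(InputError):
    """Invalid experimental-design specification."""


class FitError(CombifitError):
    """A model fit failed or produced an unusable result."""


class RangeError(CombifitError):
    """Prediction requested grossly outside the fitted design region."""
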