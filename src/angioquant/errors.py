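"""Exception types shared across the package."""


class AngioquantError(Exception):
    """Base class for package-specific errors."""


class ColorAmbiguityError(AngioquantError):
    """A pixel lies within tolerance of two reference colors (tolerance too large)."""


class MissingReferenceError(AngioquantError):
    """No central vein annotation found; ingrowth distances cannot be computed."""


class PackingError(AngioquantError):
    """Synthetic capillary placement failed after the attempt budget."""


class DegenerateVarianceError(AngioquantError):
    """All groups have zero within-group variance; the F statistic is undefined."""
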