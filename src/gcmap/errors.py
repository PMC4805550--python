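"""Exception hierarchy for the gcmap pipeline."""


class GcmapError(Exception):
    """Base class for all gcmap errors."""


class InvalidGeometryError(GcmapError, ValueError):
    """Stimulation-grid geometry is unusable (non-positive step, negative extent...)."""


class DegenerateNoiseError(GcmapError, ValueError):
    """Noise-charge distribution has zero spread; Z-scores are undefined."""


class UndefinedCorrelationError(GcmapError, ValueError):
    """Pearson correlation requested on a zero-variance pattern."""


class DegenerateStructureError(GcmapError, ValueError):
    """Co-clustering requested on a matrix with no structure (constant entries)."""


class SchemaError(GcmapError, ValueError):
    """Bundle file does not match the expected on-disk schema."""
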