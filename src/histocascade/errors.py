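"""Exception hierarchy shared across the pipeline stages."""


class HistocascadeError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(HistocascadeError):
    """Invalid configuration: bad stain matrix, bad parameters, bad cascade."""


class DegenerateInputError(HistocascadeError):
    """Input is structurally valid but carries no usable signal
    (constant image, empty measurement pool, too few centroids)."""


class DegenerateGeometryError(DegenerateInputError):
    """Point set does not admit the requested geometric construction
    (too few points, all collinear)."""


class PlacementError(HistocascadeError):
    """Synthetic nuclei could not be placed within the attempt budget."""


class TrainingError(HistocascadeError):
    """A classifier could not be trained (e.g. a class group absent
    from the training split)."""


class SchemaError(HistocascadeError):
    """A feature table or report is missing required columns."""
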