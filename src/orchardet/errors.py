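"""Exception hierarchy shared by all orchardet modules."""


class OrchardetError(Exception):
    """Base class for all orchardet errors."""


class InvalidTiling(OrchardetError):
    """Tile size or stride incompatible with the image dimensions."""


class DegenerateEmbedding(OrchardetError):
    """An embedding vector with zero L2 norm cannot enter a cosine."""


class EncoderError(OrchardetError):
    """The image encoder failed on a tile.

    Carries the (row, col) index of the offending tile.
    """

    def __init__(self, message, tile_index=None):
        super().__init__(message)
        self.tile_index = tile_index


class NoSalientRegion(OrchardetError):
    """The attention heatmap is degenerate or nothing survives thresholding."""


class NoPromptsError(OrchardetError):
    """Mask generation was requested with an empty prompt set."""


class SegmenterError(OrchardetError):
    """The promptable segmenter backend failed."""


class InvalidSeed(OrchardetError):
    """A region-growing seed lies outside the image."""


class NumericalError(OrchardetError):
    """Non-finite parameters or an ill-posed normalization state."""


class ShapeError(OrchardetError):
    """Array shapes incompatible with the requested operation."""


class InvalidBox(OrchardetError):
    """A degenerate (zero or negative area) bounding box."""


class UnknownClass(OrchardetError):
    """A class name absent from the class registry."""


class PlacementError(OrchardetError):
    """Scene synthesis could not place objects under the spec constraints."""


class DatasetError(OrchardetError):
    """A dataset directory is missing required images or labels."""


class FormatError(OrchardetError):
    """A file does not conform to its on-disk format."""


class ConfigError(OrchardetError):
    """A run configuration fails schema validation."""
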