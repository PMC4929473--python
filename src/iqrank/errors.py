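"""Exception hierarchy for iqrank."""


class IQRankError(Exception):
    """Base class for all iqrank errors."""


class ImageLoadError(IQRankError):
    """An image file could not be read or has an unsupported layout."""


class EmptyDatasetError(IQRankError):
    """A dataset directory contained no matching image files."""


class ParameterError(IQRankError, ValueError):
    """A parameter value violates an operation's contract."""
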