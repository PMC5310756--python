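import numpy as np

from dynasig.series_prep import PreparedSeries, RawSeries


def make_raw(values, category="synthetic_linear", sid="s", start_year=1950):
    values = np.asarray(values, dtype=float)
    return RawSeries(
        id=sid,
        category=category,
        years=np.arange(start_year, start_year + len(values)),
        values=values,
    )


def make_prepared(values, category="synthetic_linear", sid="s"):
    """Wrap arbitrary values as a PreparedSeries (tests bypass prepare())."""
    return PreparedSeries(id=sid, category=category, values=np.asarray(values, float))
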