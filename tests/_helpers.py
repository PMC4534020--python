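import numpy as np


def true_contig_position(contig, dataset):
    """Median genomic midpoint of a contig's target-origin members."""
    mids = [
        (dataset.truth.bac_position[m.bac_id][1] + dataset.truth.bac_position[m.bac_id][2]) / 2
        for m in contig.members
        if dataset.truth.bac_position[m.bac_id][0] == dataset.model.name
    ]
    return float(np.median(mids)) if mids else np.nan
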