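"""Small reference datasets bundled with the package.

``NETWORK_SUMMARY`` holds published summary statistics of five soil
bacterial co-occurrence networks sampled at increasing distance from an
underground-mining disturbance (groups H0..H5). The columns are the node
and signed-edge counts together with the derived topology statistics as
printed; they are useful as worked examples and as a consistency check of
the arithmetic identities average_degree = 2E/N and
density = 2E/(N(N-1)).
"""

import pandas as pd

NETWORK_SUMMARY = pd.DataFrame(
    {
        "nodes": [241, 240, 240, 240, 237],
        "edges": [1299, 1104, 567, 675, 653],
        "positive_edges": [735, 584, 417, 442, 351],
        "negative_edges": [564, 520, 150, 233, 302],
        "average_degree": [10.7801, 9.2000, 4.7250, 5.6250, 5.5105],
        "average_path_length": [3.8889, 5.1753, 6.1269, 6.4792, 5.3874],
        "network_diameter": [12, 14, 15, 17, 14],
        "network_density": [0.0449, 0.0385, 0.0198, 0.0235, 0.0233],
        "clustering_coefficient": [0.5222, 0.5311, 0.4764, 0.5304, 0.4437],
    },
    index=pd.Index(["H0", "H1", "H2", "H3", "H5"], name="group"),
)
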