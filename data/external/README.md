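# External benchmark graphs

The classical community-detection benchmarks are published datasets that
are not redistributed with this package. To run the external checks
(`tests/test_acceptance.py::test_external_benchmark_modularities`) and to
have `scripts/acceptance.py` include them, download and place here:

| file | graph | nodes / edges |
|---|---|---|
| `dolphins.gml` | Doubtful Sound dolphin social network | 62 / 159 |
| `polbooks.gml` | US politics books co-purchasing | 105 / 441 |
| `football.gml` | American college football schedule | 115 / 613 |
| `jazz.edgelist` | jazz musician collaborations | 198 / 2742 |

GML files are read as-is; plain edge lists (whitespace-separated, `#`
comments) work via the `.edgelist` or `.txt` suffix. The usual sources
are M. E. J. Newman's network-data page and the Arenas network
repository (for jazz).
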