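import json

import pytest


@pytest.fixture
def toy_panel_files(tmp_path):
    """A 3-strain, 1-trait panel on disk: host, donor, one CSS; 4 animals each."""
    csv = tmp_path / "phenotypes.csv"
    rows = ["strain,trait,sex,animal,value"]
    values = {"B6": [1, 2, 3, 4], "PWD": [9, 10, 11, 10], "CSS1": [5, 6, 5, 6]}
    for strain, vals in values.items():
        for i, v in enumerate(vals):
            rows.append(f"{strain},bw,M,a{i},{v}")
    csv.write_text("\n".join(rows) + "\n")

    config = tmp_path / "panel.json"
    config.write_text(
        json.dumps(
            {
                "panel_id": "toy",
                "host": "B6",
                "donor": "PWD",
                "css": [{"strain": "CSS1", "chromosome": "1"}],
            }
        )
    )
    return csv, config
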