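import pytest

from rbpscreen.array_io import SpotRecord, scan_from_spots

# 8-spot fixture: 3 proteins in duplicate + 2 positive controls.
GPR_FIXTURE = "\n".join([
    "ATF\t1.0",
    "2\t8",
    '"Type=GenePix Results 3"',
    '"BlockCount=1"',
    '"Block"\t"Row"\t"Column"\t"ID"\t"Name"\t"F635 Median"\t"B635 Median"\t"Flags"',
    '1\t1\t1\t"CTRL1"\t"Anti-Human IgG Control"\t50000\t500\t0',
    '1\t1\t2\t"CTRL2"\t"Alexa Fluor 647 BSA"\t48000\t480\t0',
    '1\t1\t3\t"NM_0001"\t"protein alpha"\t1500\t500\t0',
    '1\t1\t4\t"NM_0001"\t"protein alpha"\t1700\t500\t0',
    '1\t2\t1\t"NM_0002"\t"protein beta"\t500\t500\t0',
    '1\t2\t2\t"NM_0002"\t"protein beta"\t520\t500\t0',
    '1\t2\t3\t"NM_0003"\t"protein gamma"\t2500\t1000\t0',
    '1\t2\t4\t"NM_0003"\t"protein gamma"\t2600\t1000\t-100',
]) + "\n"


@pytest.fixture
def gpr_file(tmp_path):
    path = tmp_path / "fixture.gpr"
    path.write_text(GPR_FIXTURE)
    return path


def make_scan(mean_ratios, rna_id="TP53", strand="sense", b635=1000.0):
    """A minimal duplicate-spot scan whose per-protein ratios are given.

    ``mean_ratios`` maps protein_id -> (ratio_spot1, ratio_spot2) or a
    single ratio applied to both duplicates.
    """
    spots = []
    for i, (pid, ratios) in enumerate(sorted(mean_ratios.items())):
        if isinstance(ratios, (int, float)):
            ratios = (ratios, ratios)
        for j, r in enumerate(ratios):
            spots.append(SpotRecord(
                block=1, row=i + 1, column=j + 1,
                protein_id=pid, protein_name=f"protein {pid}",
                f635=b635 * r, b635=b635,
            ))
    return scan_from_spots(spots, scan_id=f"{rna_id}_{strand}",
                           rna_id=rna_id, strand=strand)


@pytest.fixture
def ratio_scan():
    return make_scan
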