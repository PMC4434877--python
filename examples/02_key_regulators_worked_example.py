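"""Key-regulator set logic on the bundled depression-subtype tables.

Reproduces the downstream set logic of a published two-subtype depression
study: individual-effect exclusion of the DRG lists, then overlap of the
disease DRGs with the TF->target DCL tables into the key regulators.
"""

from dcreg import exclude_shared, key_overlap
from dcreg.datasets import (
    MDD_POST_DRGS,
    MDD_PRE_DRGS,
    SSD_POST_DRGS,
    SSD_PRE_DRGS,
    mdd_tf2target_dcls,
    ssd_tf2target_dcls,
)

for name, pre, post, table in (
    ("MDD", MDD_PRE_DRGS, MDD_POST_DRGS, mdd_tf2target_dcls(retained_only=True)),
    ("SSD", SSD_PRE_DRGS, SSD_POST_DRGS, ssd_tf2target_dcls(retained_only=True)),
):
    drgs = exclude_shared(pre, post)
    key_drgs, key_drls = key_overlap(drgs, table)
    print(f"{name}: {len(pre)} pre-treatment DRGs - {len(pre & post)} shared with "
          f"post-treatment -> {len(drgs)} disease DRGs")
    print(f"  disease DRGs: {', '.join(sorted(drgs))}")
    print(f"  key overlap: {len(key_drgs)} key DRG(s) "
          f"({', '.join(sorted(key_drgs))}) driving {len(key_drls)} key DRLs\n")

print("Regulators found before but not after treatment are attributed to the "
      "disease; a DRL is 'key' when its TF is itself such a disease DRG.")
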