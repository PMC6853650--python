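"""Save and restore an analysis view as a versioned JSON bookmark.

A bookmark records, per gene, the transcript shown, the visible protein
features, the active variant filter and any hand-picked variant keys —
enough to reproduce the view in a later session.
"""

from varlollipop import (
    Bookmark,
    BookmarkEntry,
    CrossRefKey,
    VariantFilter,
    load_bookmark,
    save_bookmark,
)

bookmark = Bookmark(entries=[
    BookmarkEntry(
        gene_id="G001",
        transcript_id="G001.t1",
        shown_features=["TOY1_dom1"],
        variant_filter=VariantFilter(
            allowed_consequences=frozenset({"missense_variant", "stop_gained"}),
            gnomad_af_max=0.01,
        ),
        custom_keep=[CrossRefKey("T", 117, "G", "T")],
    ),
])

text = save_bookmark(bookmark)
print(text)

restored = load_bookmark(text)
assert restored.entries == bookmark.entries
print(f"round-trip ok: {len(restored.entries)} entry restored exactly")

# The schema is versioned: a newer minor version loads with a warning, a
# different major version is refused, and unknown keys are ignored.
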