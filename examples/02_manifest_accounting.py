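"""Account for the packaged 47-specimen manifest.

Reads the specimen table shipped with the package (species, locality,
voucher, and H3/16S/COI GenBank accessions) and prints the dataset-level
counts a study reports: deposited sequences, specimens, species, genera.
"""

from rna2dbarcode import count_manifest, packaged_manifest_path, read_manifest

entries = read_manifest(packaged_manifest_path())
counts = count_manifest(entries)
print(f"specimens (rows):        {counts['n_specimens']}")
print(f"deposited accessions:    {counts['n_sequences']}")
print(f"distinct species:        {counts['n_species']}")
print(f"distinct genera:         {counts['n_genera']}")

dondice = [e for e in entries if e.genus == "Dondice"]
print(f"\nDondice specimens: {len(dondice)}; e.g. {dondice[0].species}"
      f" (voucher {dondice[0].voucher}, 16S {dondice[0].accession_by_marker['16S']})")
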