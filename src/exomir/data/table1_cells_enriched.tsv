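category	mirna
DKO-1	hsa-miR-548u
DKO-1	hsa-miR-16-1-3p
DKO-1	hsa-miR-33a-3p
DKO-1	hsa-miR-33a-5p
DKO-1	hsa-miR-31-5p
DKO-1	hsa-miR-181b-3p
DKO-1	hsa-miR-450a-5p
DKO-1	hsa-miR-424-5p
DKO-1	hsa-miR-9-5p
DKO-1	hsa-miR-219-5p
DKO-1	hsa-miR-190a
DKO-1	hsa-miR-573
DKO-1	hsa-miR-30d-3p
DKO-1	hsa-miR-204-5p
DKO-1	hsa-miR-1226-3p
DKO-1	hsa-miR-499a-5p
DKO-1	hsa-miR-450b-5p
DKO-1	hsa-miR-499b-3p
DKO-1	hsa-miR-3662
DKO-1	hsa-miR-20a-3p
DKO-1	hsa-miR-27b-5p
DKO-1	hsa-miR-5701
DKO-1	hsa-miR-4677-3p
DKO-1	hsa-let-7i-5p
DKO-1	hsa-miR-331-3p
DKO-1	hsa-miR-31-3p
DKO-1	hsa-miR-651
DKO-1	hsa-miR-1306-5p
DKO-1	hsa-miR-147b
DKO-1	hsa-miR-3611
DKO-1	hsa-miR-1305
DKO-1	hsa-miR-148a-3p
DKO-1	hsa-miR-27b-3p
DKO-1	hsa-miR-1306-3p
DKO-1	hsa-miR-374b-3p
DKO-1	hsa-miR-1260b
DKO-1	hsa-miR-3940-3p
DKO-1	hsa-miR-200c-5p
DKO-1	hsa-miR-548ar-3p
DKs-8	hsa-miR-132-5p
DKs-8	hsa-miR-484
DKs-8	hsa-miR-374a-5p
DKs-8	hsa-miR-1180
DKs-8	hsa-miR-1307-3p
DKs-8	hsa-miR-200a-5p
DKs-8	hsa-miR-548o-3p
DKs-8	hsa-miR-149-5p
DKs-8	hsa-miR-3615
DKs-8	hsa-miR-100-5p
DKs-8	hsa-miR-197-3p
DKs-8	hsa-miR-378a-5p
DKs-8	hsa-let-7a-3p
DLD-1	hsa-miR-141-3p
DLD-1	hsa-miR-26b-5p
DLD-1	hsa-miR-24-3p
DLD-1	hsa-miR-3074-5p
DLD-1	hsa-miR-15a-5p
DLD-1	hsa-miR-27a-3p
DLD-1	hsa-miR-3613-5p
DLD-1	hsa-miR-30b-5p
DLD-1	hsa-miR-29a-3p
DLD-1	hsa-miR-301a-5p
DLD-1	hsa-let-7i-3p
DLD-1	hsa-miR-185-5p
DLD-1	hsa-let-7g-5p
DLD-1	hsa-miR-23b-3p
DLD-1	hsa-miR-22-3p
DKO-1 and DKs-8	hsa-miR-141-5p
DKO-1 and DKs-8	hsa-miR-582-5p
DKO-1 and DLD-1	hsa-miR-556-3p
DKO-1 and DLD-1	hsa-miR-374a-3p
DKO-1 and DLD-1	hsa-miR-106b-5p
DKO-1 and DLD-1	hsa-miR-17-3p
DKO-1 and DLD-1	hsa-miR-24-1-5p
DKO-1 and DLD-1	hsa-miR-340-3p
DLD-1 and DKs-8	hsa-miR-24-2-5p
DLD-1 and DKs-8	hsa-miR-106a-5p
DLD-1 and DKs-8	hsa-miR-30e-5p
DLD-1 and DKs-8	hsa-miR-107
DLD-1 and DKs-8	hsa-miR-429
DLD-1 and DKs-8	hsa-miR-98-5p
DLD-1 and DKs-8	hsa-miR-425-5p
DLD-1 and DKs-8	hsa-miR-140-5p
DLD-1 and DKs-8	hsa-miR-93-5p
DLD-1 and DKs-8	hsa-miR-210
DLD-1 and DKs-8	hsa-miR-126-3p
DLD-1 and DKs-8	hsa-miR-194-5p
DLD-1 and DKs-8	hsa-miR-29b-3p
DLD-1 and DKs-8	hsa-miR-15b-5p
DLD-1 and DKs-8	hsa-miR-362-5p
DLD-1 and DKs-8	hsa-miR-27a-5p
DLD-1 and DKs-8	hsa-miR-454-3p
DLD-1 and DKs-8	hsa-miR-452-5p
DLD-1 and DKs-8	hsa-miR-196b-5p
DKO-1, DLD-1 and DKs-8	hsa-miR-32-5p
DKO-1, DLD-1 and DKs-8	hsa-miR-582-3p
DKO-1, DLD-1 and DKs-8	hsa-miR-542-3p
DKO-1, DLD-1 and DKs-8	hsa-miR-96-5p
DKO-1, DLD-1 and DKs-8	hsa-miR-101-3p
DKO-1, DLD-1 and DKs-8	hsa-miR-18a-5p
DKO-1, DLD-1 and DKs-8	hsa-miR-3529-3p
DKO-1, DLD-1 and DKs-8	hsa-miR-7-5p
DKO-1, DLD-1 and DKs-8	hsa-miR-19a-3p
DKO-1, DLD-1 and DKs-8	hsa-miR-142-3p
DKO-1, DLD-1 and DKs-8	hsa-miR-20a-5p
DKO-1, DLD-1 and DKs-8	hsa-miR-32-3p
DKO-1, DLD-1 and DKs-8	hsa-miR-130b-5p
DKO-1, DLD-1 and DKs-8	hsa-miR-1278
DKO-1, DLD-1 and DKs-8	hsa-miR-7-1-3p
DKO-1, DLD-1 and DKs-8	hsa-miR-590-3p
DKO-1, DLD-1 and DKs-8	hsa-miR-4473
DKO-1, DLD-1 and DKs-8	hsa-miR-17-5p
DKO-1, DLD-1 and DKs-8	hsa-miR-103a-3p
DKO-1, DLD-1 and DKs-8	hsa-miR-103b
DKO-1, DLD-1 and DKs-8	hsa-miR-19b-3p
DKO-1, DLD-1 and DKs-8	hsa-miR-340-5p
DKO-1, DLD-1 and DKs-8	hsa-miR-200a-3p
DKO-1, DLD-1 and DKs-8	hsa-miR-34a-5p
DKO-1, DLD-1 and DKs-8	hsa-miR-372
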