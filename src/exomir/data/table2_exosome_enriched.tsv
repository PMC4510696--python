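category	mirna
DKO-1	hsa-miR-139-5p
DKO-1	hsa-miR-3178
DKO-1	hsa-miR-151b
DKO-1	hsa-miR-125b-1-3p
DKO-1	hsa-miR-193b-3p
DKO-1	hsa-miR-935
DKO-1	hsa-miR-130b-3p
DKO-1	hsa-miR-628-3p
DKO-1	hsa-miR-139-3p
DKO-1	hsa-let-7d-3p
DKO-1	hsa-miR-589-3p
DKO-1	hsa-miR-4532
DKO-1	hsa-miR-451a
DKO-1	hsa-miR-6087
DKO-1	hsa-miR-151a-5p
DKO-1	hsa-miR-940
DKO-1	hsa-miR-222-3p
DKO-1	hsa-miR-766-5p
DKO-1	hsa-miR-505-5p
DKO-1	hsa-miR-3187-3p
DKO-1	hsa-miR-125a-3p
DKO-1	hsa-miR-3679-5p
DKO-1	hsa-miR-4436b-3p
DKO-1	hsa-miR-4787-3p
DKO-1	hsa-miR-2277-3p
DKO-1	hsa-miR-361-5p
DKO-1	hsa-miR-1293
DKO-1	hsa-miR-3183
DKO-1	hsa-miR-3162-5p
DKO-1	hsa-miR-642a-3p
DKO-1	hsa-miR-642b-5p
DKO-1	hsa-miR-197-5p
DKO-1	hsa-miR-324-3p
DKO-1	hsa-miR-145-3p
DKO-1	hsa-miR-3182
DKO-1	hsa-miR-3127-3p
DKO-1	hsa-miR-3127-5p
DKO-1	hsa-miR-4728-3p
DKO-1	hsa-miR-3184-5p
DKO-1	hsa-miR-125b-5p
DKO-1	hsa-miR-186-5p
DKO-1	hsa-miR-1
DKO-1	hsa-miR-100-5p
DKO-1	hsa-miR-423-3p
DKO-1	hsa-miR-766-3p
DKO-1	hsa-miR-4753-5p
DKO-1	hsa-miR-145-5p
DKO-1	hsa-miR-4724-5p
DKO-1	hsa-miR-373-3p
DKO-1	hsa-miR-223-5p
DKO-1	hsa-miR-1307-5p
DKO-1	hsa-miR-1914-3p
DKO-1	hsa-miR-3121-3p
DKO-1	hsa-miR-3613-3p
DKO-1	hsa-miR-205-5p
DKO-1	hsa-miR-98-3p
DKO-1	hsa-miR-23a-3p
DKO-1	hsa-miR-3124-5p
DKO-1	hsa-miR-3656
DKO-1	hsa-miR-3918
DKO-1	hsa-miR-4449
DKO-1	hsa-miR-378c
DKO-1	hsa-miR-3138
DKO-1	hsa-miR-1910
DKO-1	hsa-miR-3174
DKO-1	hsa-miR-4466
DKO-1	hsa-miR-3679-3p
DKO-1	hsa-miR-3200-5p
DKO-1	hsa-miR-6511b-5p
DKO-1	hsa-miR-1247-5p
DKO-1	hsa-miR-22-3p
DKO-1	hsa-miR-877-5p
DKO-1	hsa-miR-4687-3p
DKO-1	hsa-miR-1292-5p
DKO-1	hsa-miR-181c-5p
DKO-1	hsa-miR-6131
DKO-1	hsa-miR-6513-5p
DKO-1	hsa-miR-3661
DKO-1	hsa-miR-132-3p
DKO-1	hsa-miR-214-3p
DKO-1	hsa-miR-574-3p
DKO-1	hsa-miR-3190-3p
DKO-1	hsa-miR-326
DKO-1	hsa-miR-3191-5p
DKO-1	hsa-miR-3198
DKO-1	hsa-miR-3928
DKO-1	hsa-miR-629-3p
DKO-1	hsa-miR-4489
DKO-1	hsa-miR-4700-5p
DKO-1	hsa-miR-5006-5p
DKO-1	hsa-miR-5088
DKO-1	hsa-miR-2110
DKO-1	hsa-miR-3911
DKO-1	hsa-miR-3146
DKs-8	hsa-miR-1224-5p
DKs-8	hsa-let-7b-5p
DKs-8	hsa-miR-155-5p
DKs-8	hsa-let-7c
DKs-8	hsa-let-7a-5p
DKs-8	hsa-miR-146b-5p
DKs-8	hsa-miR-4647
DKs-8	hsa-miR-4494
DKs-8	hsa-miR-711
DKs-8	hsa-miR-1263
DLD-1	hsa-miR-1226-5p
DLD-1	hsa-miR-4745-5p
DLD-1	hsa-miR-4435
DLD-1	hsa-miR-939-5p
DLD-1	hsa-miR-409-3p
DLD-1	hsa-miR-1304-3p
DKO-1 and DKs-8	hsa-miR-146a-5p
DKO-1 and DKs-8	hsa-miR-4508
DKO-1 and DKs-8	hsa-miR-224-5p
DKO-1 and DKs-8	hsa-miR-4429
DKO-1 and DKs-8	hsa-miR-222-5p
DKO-1 and DKs-8	hsa-miR-629-5p
DKO-1 and DKs-8	hsa-miR-4492
DKO-1 and DKs-8	hsa-miR-3653
DKO-1 and DKs-8	hsa-miR-320a
DKO-1 and DKs-8	hsa-miR-1290
DKO-1 and DKs-8	hsa-miR-1262
DKO-1 and DKs-8	hsa-miR-5010-5p
DKO-1 and DKs-8	hsa-miR-204-3p
DKO-1 and DKs-8	hsa-miR-4461
DKO-1 and DKs-8	hsa-miR-5187-5p
DKO-1 and DLD-1	hsa-miR-483-5p
DKO-1 and DLD-1	hsa-miR-4658
DKO-1 and DLD-1	hsa-miR-4758-5p
DKO-1 and DLD-1	hsa-miR-492
DKO-1 and DLD-1	hsa-miR-5001-5p
DKO-1 and DLD-1	hsa-miR-371a-5p
DKO-1 and DLD-1	hsa-miR-1323
DKO-1 and DLD-1	hsa-miR-371b-3p
DKO-1 and DLD-1	hsa-miR-501-3p
DKO-1 and DLD-1	hsa-miR-4446-3p
DKO-1 and DLD-1	hsa-miR-6511a-5p
DKO-1 and DLD-1	hsa-miR-30a-3p
DKO-1 and DLD-1	hsa-miR-4727-3p
DLD-1 and DKs-8	hsa-miR-28-3p
DLD-1 and DKs-8	hsa-miR-3934-5p
DKO-1, DLD-1 and DKs-8	hsa-miR-658
DKO-1, DLD-1 and DKs-8	hsa-miR-320d
DKO-1, DLD-1 and DKs-8	hsa-miR-4792
DKO-1, DLD-1 and DKs-8	hsa-miR-1246
DKO-1, DLD-1 and DKs-8	hsa-miR-320e
DKO-1, DLD-1 and DKs-8	hsa-miR-4516
DKO-1, DLD-1 and DKs-8	hsa-miR-320b
DKO-1, DLD-1 and DKs-8	hsa-miR-4488
DKO-1, DLD-1 and DKs-8	hsa-miR-1291
DKO-1, DLD-1 and DKs-8	hsa-miR-320c
DKO-1, DLD-1 and DKs-8	hsa-miR-4634
DKO-1, DLD-1 and DKs-8	hsa-miR-3605-5p
DKO-1, DLD-1 and DKs-8	hsa-miR-4741
DKO-1, DLD-1 and DKs-8	hsa-miR-3591-3p
DKO-1, DLD-1 and DKs-8	hsa-miR-122-5p
DKO-1, DLD-1 and DKs-8	hsa-miR-486-3p
DKO-1, DLD-1 and DKs-8	hsa-miR-184
DKO-1, DLD-1 and DKs-8	hsa-miR-223-3p
DKO-1, DLD-1 and DKs-8	hsa-miR-3651
DKO-1, DLD-1 and DKs-8	hsa-miR-486-5p
DKO-1, DLD-1 and DKs-8	hsa-miR-3180
DKO-1, DLD-1 and DKs-8	hsa-miR-3180-3p
DKO-1, DLD-1 and DKs-8	hsa-miR-3168
DKO-1, DLD-1 and DKs-8	hsa-miR-4497
DKO-1, DLD-1 and DKs-8	hsa-miR-423-5p
DKO-1, DLD-1 and DKs-8	hsa-miR-3184-3p
DKO-1, DLD-1 and DKs-8	hsa-miR-150-5p
DKO-1, DLD-1 and DKs-8	hsa-miR-664a-5p
DKO-1, DLD-1 and DKs-8	hsa-miR-182-5p
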