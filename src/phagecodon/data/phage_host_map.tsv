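# Per-phage host-strain assignment. Single-strain genera are forced;
# multi-strain assignments are best-effort (synthetic where the source
# metadata does not record the pairing) and may be edited by the user.
phage_accession	host_accession
NC_054931.1	NC_000913.3
NC_000866.4	NC_000913.3
NC_005859.1	NC_000913.3
NC_054907.1	NC_000913.3
NC_001416.1	NC_000913.3
NC_001604.1	NC_000913.3
NC_001420.2	NC_000913.3
NC_001422.1	NC_000913.3
NC_001890.1	NC_000913.3
NC_048196.1	NC_000913.3
OL960580.1	NC_000913.3
PP434429.1	NC_000913.3
MZ726792.1	NC_000913.3
MK327930.1	NC_000913.3
MK562504.1	NC_000913.3
MN895436.1	NC_000913.3
MN895435.1	NC_000913.3
NC_054934.1	NC_000913.3
NC_054933.1	NC_000913.3
OP611477.1	NC_000913.3
NC_024786.1	NC_000913.3
NC_027381.1	NC_000913.3
NC_002167.1	NC_000913.3
NC_005856.1	NC_000913.3
NC_005344.1	NC_004741.1
NC_054636.1	NC_004741.1
NC_047848.1	NC_004741.1
NC_042017.1	NC_004741.1
NC_042075.1	NC_004741.1
MF158041.1	NC_004741.1
MF158043.1	NC_004741.1
NC_042076.1	NC_004741.1
MF158044.1	NC_004741.1
MF327005.1	NC_004741.1
MF327006.1	NC_004741.1
NC_042077.1	NC_004741.1
NC_042039.1	NC_004741.1
NC_054941.1	NC_004741.1
NC_042078.1	NC_004741.1
MF327009.1	NC_004741.1
OM858838.1	NC_004741.1
NC_070850.1	NC_004741.1
MK562502.1	NC_004741.1
MK562505.1	NC_004741.1
NC_047998.1	NC_004741.1
NC_021857.1	NC_004741.1
NC_003444.1	NC_004741.1
NC_025434.1	NC_004741.1
NC_005282.1	NC_016810.1
MZ150758.1	NC_016810.1
NC_020416.1	NC_016810.1
MF370225.1	NC_016810.1
NC_002371.2	NC_016810.1
PP034127.1	NC_016810.1
MZ520832.1	NC_016810.1
NC_004348.1	NC_016810.1
NC_019530.1	NC_016810.1
MT074476.1	NC_016810.1
NC_049504.1	NC_016810.1
NC_049502.1	NC_016810.1
NC_049501.1	NC_016810.1
NC_049499.1	NC_016810.1
NC_049506.1	NC_016810.1
NC_049505.1	NC_016810.1
NC_049508.1	NC_016810.1
NC_049507.1	NC_016810.1
NC_048110.1	NC_016810.1
NC_073174.1	NC_016810.1
MG251391.1	NC_016810.1
MG251392.1	NC_016810.1
NC_041970.1	NC_008596.1
NC_021299.1	NC_008596.1
NC_041971.1	NC_008596.1
MH779498.1	NC_008596.1
MK450429.1	NC_008596.1
MH779502.1	NC_008596.1
NC_023602.1	NC_008596.1
NC_023600.1	NC_008596.1
MF919539.1	NC_008596.1
NC_054785.1	NC_008596.1
MT310858.1	NC_008596.1
OM203162.1	NC_008596.1
MK494108.1	NC_008596.1
MK310141.1	NC_008596.1
MF472893.1	NC_008596.1
OR475256.1	NC_008596.1
PP750962.1	NC_008596.1
PP750964.1	NC_008596.1
NC_054714.1	NC_008596.1
PQ412543.1	NC_008596.1
NC_004687.1	NC_008596.1
NC_011048.1	NC_000964.3
NC_031245.1	NC_000964.3
NC_020883.1	NC_000964.3
NC_021856.1	NC_000964.3
NC_048631.1	NC_000964.3
NC_011421.1	NC_000964.3
NC_022761.1	NC_000964.3
NC_043027.1	NC_000964.3
NC_048652.1	NC_000964.3
KY368639.1	NC_000964.3
NC_048726.1	NC_000964.3
NC_022771.1	NC_000964.3
MF422185.1	NC_000964.3
NC_007458.1	NZ_CP138336.1
NC_011645.1	NZ_CP138336.1
NC_017976.1	NZ_CP138336.1
NC_018856.1	NZ_CP138336.1
NC_071041.1	NZ_CP138336.1
NC_018860.1	NZ_CP138336.1
NC_020873.1	NZ_CP138336.1
NC_070841.1	NZ_CP138336.1
NC_027352.1	NZ_CP138336.1
NC_027355.1	NZ_CP138336.1
NC_002486.1	NC_007795.1
NC_002321.1	NC_007795.1
NC_009875.1	NC_007795.1
NC_014460.1	NC_007795.1
NC_009526.1	NC_007795.1
MT151386.1	NC_007795.1
NC_047728.1	NC_007795.1
NC_023009.1	NC_007795.1
KJ206559.1	NC_007795.1
MF398190.1	NC_007795.1
NC_022920.1	NC_007795.1
NC_005880.2	NC_007795.1
NC_025426.1	NC_007795.1
NC_025417.1	NC_007795.1
MN045228.1	NC_007795.1
MW528836.1	NC_007795.1
LC680885.1	NC_007795.1
LC574321.1	NC_007795.1
MW349128.1	NC_007795.1
NC_020877.1	NC_007795.1
NC_022090.1	NC_007795.1
NC_047720.1	NC_007795.1
NC_047729.1	NC_007795.1
NC_012530.1	NC_022112.1
NC_028835.1	NC_022112.1
NC_028783.1	NC_004567.1
NC_028830.1	NC_004567.1
NC_005893.1	NC_022112.1
NC_048752.1	NC_004567.1
NC_048753.1	NC_004567.1
NC_048754.1	NC_004567.1
NC_047926.1	NC_004567.1
NC_047924.1	NC_004567.1
NC_048084.1	NC_004567.1
MH809530.1	NC_004567.1
NC_048085.1	NC_004567.1
NC_047764.1	NC_004567.1
NC_019916.1	NZ_LS483405.1
NC_047739.1	NC_004567.1
NC_006565.1	NC_004567.1
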