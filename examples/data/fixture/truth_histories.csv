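# migroute 0.1.0 simulate config=d07668e785
tag_id,species,tag_type,occ1,occ2,occ3,occ4,occ5,occ6,occ7,occ8,occ9,occ10,occ11,occ12,occ13,occ14,occ15,occ16,occ17,occ18,occ19,occ20,occ21,occ22,occ23,occ24,occ25,occ26,occ27,occ28,occ29,occ30,occ31,occ32,occ33,occ34,occ35,occ36
EurasianBlackbird-001,Thrushes,ACT,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,3,4,4,4,4,4,4,4,4
SongThrush-001,Thrushes,ACT,1,1,1,1,1,1,1,1,1,1,3,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4
Redwing-001,Thrushes,ACT,1,1,1,1,1,1,3,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4
Blackcap-001,Blackcap,NTQB,1,1,1,1,1,1,1,1,1,3,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4
Blackcap-002,Blackcap,NTQB,1,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4
GardenWarbler-001,Garden Warbler,NTQB,1,3,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4
GardenWarbler-002,Garden Warbler,NTQB,1,1,3,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4
NorthernWheatear-001,Northern Wheatear,NTQB,1,1,1,1,3,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4,4
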