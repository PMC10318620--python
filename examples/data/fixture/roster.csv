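# migroute 0.1.0 simulate config=d07668e785
tag_id,species,model_group,distance_group,tag_type,individual,determined,departure_occasion,route_true,observed_code
Dunnock-001,Dunnock,Dunnock,short,NTQB,0,False,2,offshore,4
EurasianBlackbird-001,Eurasian Blackbird,Thrushes,short,ACT,1,True,28,onshore,3
SongThrush-001,Song Thrush,Thrushes,short,ACT,2,True,11,onshore,3
Redwing-001,Redwing,Thrushes,short,ACT,3,True,7,onshore,3
Blackcap-001,Blackcap,Blackcap,short,NTQB,4,True,10,onshore,3
Blackcap-002,Blackcap,Blackcap,short,NTQB,5,True,2,offshore,4
Blackcap-003,Blackcap,Blackcap,short,NTQB,6,False,5,onshore,3
GardenWarbler-001,Garden Warbler,Garden Warbler,long,NTQB,7,True,2,onshore,3
GardenWarbler-002,Garden Warbler,Garden Warbler,long,NTQB,8,True,3,onshore,3
NorthernWheatear-001,Northern Wheatear,Northern Wheatear,long,NTQB,9,True,5,onshore,3
NorthernWheatear-002,Northern Wheatear,Northern Wheatear,long,NTQB,10,False,2,offshore,2
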