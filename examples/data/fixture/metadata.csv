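# migroute 0.1.0 simulate config=d07668e785
tag_id,species,model_group,distance_group,tag_type,deployment_time,deployment_lat,deployment_lon
Dunnock-001,Dunnock,Dunnock,short,NTQB,2021-04-01 09:00:00,53.6,8.0
EurasianBlackbird-001,Eurasian Blackbird,Thrushes,short,ACT,2021-04-01 09:00:00,53.6,8.0
SongThrush-001,Song Thrush,Thrushes,short,ACT,2021-04-01 09:00:00,53.6,8.0
Redwing-001,Redwing,Thrushes,short,ACT,2021-04-01 09:00:00,53.6,8.0
Blackcap-001,Blackcap,Blackcap,short,NTQB,2021-04-01 09:00:00,53.6,8.0
Blackcap-002,Blackcap,Blackcap,short,NTQB,2021-04-01 09:00:00,53.6,8.0
Blackcap-003,Blackcap,Blackcap,short,NTQB,2021-04-01 09:00:00,53.6,8.0
GardenWarbler-001,Garden Warbler,Garden Warbler,long,NTQB,2021-04-01 09:00:00,53.6,8.0
GardenWarbler-002,Garden Warbler,Garden Warbler,long,NTQB,2021-04-01 09:00:00,53.6,8.0
NorthernWheatear-001,Northern Wheatear,Northern Wheatear,long,NTQB,2021-04-01 09:00:00,53.6,8.0
NorthernWheatear-002,Northern Wheatear,Northern Wheatear,long,NTQB,2021-04-01 09:00:00,53.6,8.0
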